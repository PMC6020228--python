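"""Generate the synthetic study inputs and record their ground truth.

Builds the toy β-barrel (with and without the axial palmitate stand-in),
an elastic-network ensemble exemplar, the two-state barrel-opening series,
and noise-free/noisy one-site binding curves.  Bulky coordinate data are
regenerated on demand by the later scripts (every generator is seeded), so
this step writes only compact exemplars and a manifest of the generating
parameters under results/data/.
"""

import json
from pathlib import Path

from portalwatch.structure_io import trajectory_to_structures, write_pdb
from portalwatch.synthetic_data import (DEFAULT_SPR_CONCENTRATIONS,
                                        EnsembleSpec, OpeningSpec,
                                        build_toy_barrel,
                                        ensemble_from_structure,
                                        simulate_binding, simulate_opening)

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
OUT.mkdir(parents=True, exist_ok=True)

SEED = 2024
TABLE_PARAMS = {"wt": (1466.0, 3.1), "f57a": (1408.0, 6.2)}

manifest = {"seed": SEED}

# toy barrels: 10 antiparallel strands of Cα/Cβ pseudo-residues
barrel = build_toy_barrel()
barrel_lig = build_toy_barrel(with_ligand=True)
(OUT / "toy_barrel.pdb").write_text(write_pdb(barrel))
(OUT / "toy_barrel_ligand.pdb").write_text(write_pdb(barrel_lig))
manifest["toy_barrel"] = {"n_residues": 60, "n_strands": 10, "ligand_atoms": 16}
print(f"toy barrel: {len(barrel)} atoms (+16 ligand carbons in the liganded copy)")

# elastic-network ensemble exemplar: 5 frames as a multi-model PDB
spec = EnsembleSpec(n_frames=5, seed=SEED)
traj, _ = ensemble_from_structure(barrel, spec)
(OUT / "enm_ensemble_5frames.pdb").write_text(
    write_pdb(trajectory_to_structures(traj)))
manifest["enm_ensemble"] = {"cutoff_A": spec.cutoff, "spring": spec.spring,
                            "kT": spec.kT, "exemplar_frames": spec.n_frames,
                            "analysis_frames": 5000}
print(f"elastic-network ensemble exemplar: {traj.n_frames} frames × {traj.n_atoms} Cα")

# two-state opening series (first 500 frames as CSV exemplar)
ospec = OpeningSpec(n_frames=10_000, seed=SEED)
series, labels = simulate_opening(ospec)
lines = ["frame,distance_A,state"]
lines += [f"{f},{d:.4f},{s}" for f, d, s in
          zip(series.frame_indices[:500], series.distances[:500], labels[:500])]
(OUT / "opening_series_head.csv").write_text("\n".join(lines) + "\n")
manifest["opening_series"] = {**{k: v for k, v in series.descriptor.items()
                                 if k != "generator"},
                              "n_frames": ospec.n_frames}
print(f"opening series: {ospec.n_frames} frames, true stationary open fraction "
      f"{ospec.stationary_open_fraction:.2f}, sample fraction {labels.mean():.4f}")

# binding curves from the published equilibrium SPR parameters
for variant, (bmax, kd) in TABLE_PARAMS.items():
    clean = simulate_binding(DEFAULT_SPR_CONCENTRATIONS, bmax, kd)
    noisy = simulate_binding(DEFAULT_SPR_CONCENTRATIONS, bmax, kd,
                             noise_sd=0.02 * bmax, seed=SEED)
    (OUT / f"binding_{variant}_clean.csv").write_text(clean.to_csv())
    (OUT / f"binding_{variant}_noisy.csv").write_text(noisy.to_csv())
    print(f"binding curves ({variant}): Bmax {bmax} R.U., Kd {kd} uM, "
          f"{len(DEFAULT_SPR_CONCENTRATIONS)} concentrations 0.1-15 uM")
manifest["binding"] = {v: {"Bmax_RU": p[0], "Kd_uM": p[1]}
                       for v, p in TABLE_PARAMS.items()}

(OUT / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
print(f"wrote exemplars + manifest to {OUT}")
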
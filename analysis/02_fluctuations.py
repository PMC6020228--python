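"""RMSF and cross-correlation analysis: coordinated vs decoupled portal motion.

Samples two Gaussian ensembles over the toy barrel — one with the designed
anti-correlation between a portal block and the β5-β6-like block (wild-type
analogue), one with the coupling removed (mutant analogue) — aligns them,
and computes RMSF profiles, cross-correlation maps, and the segment-block
statistics that quantify the loss of anti-correlation.
"""

import json
from pathlib import Path

import numpy as np

from portalwatch.fluctuations import (SegmentSet, anticorrelation_loss, dccm,
                                      rmsf, segment_correlation)
from portalwatch.superpose import align_trajectory
from portalwatch.synthetic_data import (build_toy_barrel,
                                        portal_coupling_covariance,
                                        sample_ensemble)

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(parents=True, exist_ok=True)

SEED = 2024
N_FRAMES = 4000
PORTAL = list(range(24, 30))  # resids 25-30: the "helix/portal" block
B5B6 = list(range(42, 48))    # resids 43-48: the "β5-β6 flap" block
SEGMENTS = SegmentSet({"portal": (25, 30), "loop_b5b6": (43, 48)})

barrel = build_toy_barrel()
mean = np.array([a.coords for a in barrel.atoms if a.name == "CA"])
topo = [a for a in barrel.atoms if a.name == "CA"]

report = {"seed": SEED, "n_frames": N_FRAMES,
          "segments": {k: list(v) for k, v in SEGMENTS.segments.items()}}
corrs = {}
for label, coupled in (("wt_like", True), ("mutant_like", False)):
    cov, analytic = portal_coupling_covariance(mean, PORTAL, B5B6, coupled=coupled)
    traj = sample_ensemble(mean, cov, N_FRAMES,
                           seed=SEED + (0 if coupled else 1), topology=topo)
    aligned = align_trajectory(traj)

    profile = rmsf(aligned)
    (OUT / f"rmsf_{label}.csv").write_text(profile.to_csv())

    est = dccm(aligned)
    (OUT / f"dccm_{label}.csv").write_text(est.to_csv())
    analytic_err = float(np.nanmax(np.abs(est.C - analytic)))

    corr = segment_correlation(est, SEGMENTS, ("loop_b5b6", "portal"))
    corrs[label] = corr
    report[label] = {
        "rmsf_mean_A": round(float(profile.rmsf.mean()), 4),
        "rmsf_max_A": round(float(profile.rmsf.max()), 4),
        "dccm_max_abs_error_vs_analytic": round(analytic_err, 4),
        "block_mean_corr": round(corr.mean, 4),
        "block_min_corr": round(corr.min, 4),
        "pairs_below_threshold": corr.count_below_threshold,
        "n_pairs": corr.n_pairs,
    }
    print(f"{label}: block mean corr {corr.mean:+.3f} "
          f"({corr.count_below_threshold}/{corr.n_pairs} pairs ≤ "
          f"{corr.anticorr_threshold}), DCCM vs analytic max err {analytic_err:.3f}")

delta = anticorrelation_loss(corrs["wt_like"], corrs["mutant_like"])
report["anticorrelation_loss"] = {"delta_mean": round(delta.delta_mean, 4),
                                  "delta_count": delta.delta_count}
print(f"anti-correlation loss: Δmean {delta.delta_mean:+.3f}, "
      f"Δcount {delta.delta_count} — the coupled (wild-type-like) ensemble's "
      f"strong β5-β6/portal anti-correlation disappears when the coupling is removed")

(OUT / "fluctuations_report.json").write_text(json.dumps(report, indent=2) + "\n")
print(f"wrote RMSF/DCCM tables and fluctuations_report.json to {OUT}")
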
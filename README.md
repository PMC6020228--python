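# portalwatch

Trajectory- and structure-analysis tools for studying the **portal region of
fatty acid binding proteins (FABPs)** — the gate formed by helix α2 and the
β3-β4 and β5-β6 loops through which lipid ligands are thought to enter and
leave the β-barrel cavity. The package was built around the analysis of a
portal-gatekeeper mutant (Phe57→Ala) of the human myelin protein P2, where
the questions are: how do per-residue fluctuations change, is the
coordinated anti-correlated breathing of the portal region lost, does the
discontinuous barrel open between strands β4 and β5, which residues are
central in the residue interaction network, and how does equilibrium
membrane binding change?

It is organised as an analysis project: the library lives in
`src/portalwatch/`, the numbered scripts in `analysis/` run the study steps
and write their tables to `results/`, and a `portalwatch` command-line
interface exposes each analysis on files.

## What it computes

- **Superposition & RMSF** — Kabsch (SVD) rigid-body superposition with an
  iterative-mean reference, then per-residue root mean-square fluctuations
  RMSF_i = √⟨|r_i(t) − ⟨r_i⟩|²⟩ on Cα atoms.
- **Dynamic cross-correlation maps (DCCM)** —
  C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨|Δr_i|²⟩⟨|Δr_j|²⟩), with segment-block statistics
  (mean/min/max, count of pairs below an anti-correlation threshold) and a
  wild-type-vs-mutant "loss of anti-correlation" delta report.
- **Barrel-opening detection** — loop-tip distance time series (single-Cα,
  centroid, or minimum-heavy-atom modes) and event detection as maximal
  runs above a distance threshold lasting at least a dwell time.
- **Residue interaction networks (RIN)** — contacts between residues whose
  minimum heavy-atom distance falls in a 2.5–5.0 Å window; normalized
  shortest-path betweenness and removal-impact centrality
  (relative global-efficiency drop on node deletion); population Z-scores
  with a Z ≥ 2 central set; differential central residues across structure
  families; explicit flagging when a bound ligand dominates the network.
- **One-site binding fits** — Y = B_max·X/(K_d + X) by least squares with
  log-parameterized positivity, standard errors from the linearized
  covariance, and R².
- **Synthetic ground truth** (`synthetic_data`) — a toy Cα/Cβ β-barrel with
  an optional axial 16-carbon ligand; anisotropic elastic-network (ANM)
  covariances with the analytic DCCM they imply; a designed "portal
  coupling" covariance whose block anti-correlation can be switched off;
  hidden two-state Markov opening series; seeded binding curves. Every
  generator is deterministic given (parameters, seed).

## Worked example

Fit the one-site model to an equilibrium SPR-style concentration series
(0.1–15 μM) generated from the published wild-type P2 parameters:

```
$ portalwatch simulate binding --seed 4 --out spr
$ portalwatch fit-binding spr.csv
```

prints (abridged):

```json
{
  "fit": {
    "Bmax_RU": 1461.66, "Bmax_SE": 37.18,
    "Kd_uM": 3.16, "Kd_SE": 0.25,
    "R2": 0.9963, "converged": true, "n_points": 11
  },
  "model": "Y = Bmax*X/(Kd+X)"
}
```

The generating parameters were B_max = 1466 R.U. and K_d = 3.1 μM with 2 %
Gaussian noise; the fit recovers them within the reported standard errors.
Against the F57A-like parameters (K_d = 6.2 μM) the same pipeline yields a
~2-fold weaker affinity at similar saturation — the hallmark of the portal
mutant's membrane-binding change.

The full study runs as:

```
python analysis/01_simulate_inputs.py      # inputs + ground-truth manifest
python analysis/02_fluctuations.py         # RMSF, DCCM, anti-correlation loss
python analysis/03_barrel_opening.py       # two-state opening detection
python analysis/04_interaction_networks.py # RIN centralities, differential sets
python analysis/05_binding_fits.py         # one-site fits, noise sweep
```

Each script states what it found on stdout and writes machine-readable
tables under `results/`. For example, `02_fluctuations.py` reports a
β5-β6/portal block mean correlation of −0.63 for the coupled
(wild-type-like) ensemble against −0.01 for the decoupled (mutant-like)
one: the engineered loss of coordinated portal breathing is recovered by
the estimator from 4000 sampled frames.

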
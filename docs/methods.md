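# Methods

This note documents the models, conventions and numerical choices behind
`portalwatch`, and what the synthetic generators do and do not emulate.

## Structures, numbering and selections

PDB input covers ATOM/HETATM/MODEL/ENDMDL/TER. Residue numbering is taken
verbatim from the file and never renumbered; for P2-family structures this
is the conventional FABP numbering (portal-gate Phe at 57), which differs
by −1 from some mutation-report numbering — any cross-referencing is the
user's responsibility and all reports echo the residue ranges actually
used. Alternate locations other than blank/"A" are dropped so each model
has one deterministic conformer; insertion codes raise a parse error
because the intended structure family does not use them and silent
mangling would corrupt residue identity. Residue ranges are inclusive on
both ends; frames are 0-indexed. Multi-chain asymmetric units are treated
one chain at a time.

## Superposition and alignment

Superposition is the closed-form SVD (Kabsch) solution with determinant
sign correction, so a reflection is never returned; point sets must have
≥ 3 non-collinear pairs (second singular value above 1e-10 relative).
RMSD is computed from the transformed coordinates directly rather than the
trace identity, which loses half the significant digits near zero.

Trajectory alignment fits each frame on the Cα set (unit weights — mass
weighting is immaterial on Cα-only sets) against an iterative-mean
reference: start from frame 0, re-align to the mean fit-atom structure
until the mean moves < 1e-6 Å RMSD or 10 iterations. A first-frame mode is
available as a flag. The aligned ensemble is finally moved to a canonical
pose (reference centroid at the origin, orientation fixed by a
Gram-Schmidt frame over the reference geometry) so that the output is
invariant — not merely equivariant — under rigid transforms of the input.

## Fluctuations and cross-correlation

RMSF and the cross-correlation map use fluctuations about the ensemble
*mean* (not the first frame), consistent with the iterative-mean
alignment. The map uses the isotropic scalar-product definition
C_ij = ⟨Δr_i·Δr_j⟩/√(⟨|Δr_i|²⟩⟨|Δr_j|²⟩), the definition implemented by
the standard trajectory-analysis toolchain for such maps; entries are
clipped to [−1, 1], the matrix is symmetrized against roundoff and the
diagonal set to exactly 1. A residue whose variance is below 1e-12 of the
most mobile residue's has no defined correlation and is flagged missing
(NaN) rather than zeroed. No windowing or block averaging is applied: the
whole post-equilibration trajectory is one estimate.

The default equilibration cut discards the first sixth of the frames,
mirroring the convention of analysing the last 2.5 μs of a 3 μs run; it is
a flag, as is a time-based cut.

Portal segment defaults (helix α1 14–22, α2 26–34, loop β3-β4 55–60, loop
β5-β6 74–79) are configuration values for a P2-like topology, not
constants: published analyses do not print the exact ranges, so users
should validate them against their structure annotation. The
anti-correlation threshold defaults to −0.3 (exposed as a flag). Segment
block statistics exclude self-pairs; the wt-vs-mutant comparison reports
Δmean = mean_variant − mean_reference, positive on an anti-correlated
block when anti-correlation is lost.

## Opening detection

Distances are computed on unaligned coordinates (inter-group distances are
rigid-invariant, so geometry does not depend on superposition). Loop tips
default to the Cα of configured tip residues (β3-β4 tip 57, β5-β6 tip 77).
An opening event is a maximal run of frames above the distance threshold
lasting at least `min_dwell` frames; with `min_dwell` = 1 events partition
the above-threshold frames exactly. The default threshold (13 Å) and dwell
(10 frames) are tunable flags chosen to separate a closed baseline from
excursions; no automatic threshold selection is attempted. The dwell
filter biases the recovered open fraction downward by clipping short true
excursions — the event tables in `results/opening_report.json` quantify
this directly.

The gate-residue distance uses the side-chain heavy-atom centroid of the
gate residue against the helix Cα centroid; Gly/Ala gates (the mutant
case) fall back to Cα with a logged warning.

## Residue interaction networks

Contacts: residues A ≠ B are linked iff their minimum heavy-atom distance
lies in [2.5, 5.0] Å — both endpoints inclusive, the conservative reading
of a printed "2.5–5 Å" window, and configurable. A pair whose closest
atoms clash below 2.5 Å gets *no* edge; the bound applies verbatim.
Hydrogens never count; water never enters; a hetero ligand becomes a node
only on request. Sequence neighbours (|Δresid| = 1, same chain) are kept
by default with an exclusion flag. Edges are unweighted for path
computations; the contact distance is stored as metadata. The
implementation reduces KD-tree atom pairs to per-residue-pair minima and
is checked against an O(N²) brute-force scan in the tests.

Centralities: normalized shortest-path betweenness (fractional counting,
normalization (n−1)(n−2)/2) and removal impact, defined as
(E(G) − E(G∖i))/E(G) with E the global efficiency (mean over node pairs of
1/d, 1/∞ = 0). Removal impact is our documented interpretation of
"residue centrality" in structure-network tools whose exact score is not
published; betweenness is always computed alongside as the cross-check,
and neither is claimed to reproduce any specific published node list.
Z-scores use the population SD (fixed, testable convention); all Z are 0
when the SD is 0; the central set is {Z ≥ 2} on the removal-impact metric
by default, switchable to betweenness.

Differential centrality matches nodes by (resid, resname), dropping the
chain id, because variant structures from different crystal forms rarely
share chain naming; the key function is a parameter. "Gained" is the union
over variants of central keys not central in the reference; "lost"
requires absence from every variant. When a ligand is included its many
contacts typically dominate betweenness; reports carry an explicit
`ligand_dominant` flag and the analysis scripts compute centralities from
ligand-free networks.

## One-site binding fit

The model Y = B_max·X/(K_d + X) is fit by unweighted least squares
(no weighting scheme is published for the reference data). Positivity is
enforced by optimizing (log B_max, log K_d); the problem is first
normalized (X by its median, Y by its max) so the fit is exactly
equivariant under unit changes, with an analytic Jacobian — the
finite-difference default locates the optimum only to ~√ε. Initial
guesses: B_max⁰ = max Y, K_d⁰ = median X. Duplicate injections are
averaged per concentration by default (flag to fit raw rows; with balanced
duplicates the two give the same estimates). Standard errors come from
(JᵀJ)⁻¹·s² in the natural parameters at the optimum with
s² = SS_res/(n−2); R² = 1 − SS_res/SS_tot. Non-convergence within 500
evaluations raises an error carrying the last iterate. Kinetic
(on/off-rate) analysis is out of scope.

## Synthetic generators: what they emulate, and what they don't

The generators stand in for inputs that cannot be recomputed at desk
scale — microsecond atomistic MD and instrument data:

- **Toy barrel.** 10 antiparallel strands of 6 Cα/Cβ pseudo-residues on a
  cylinder with an optional 16-carbon axial ligand. The default radius
  (4.8 Å) is proportionally tighter than a real ~8 Å barrel because the
  pseudo-residues carry no side chains; it is chosen so neighbouring
  strands and the axial ligand fall inside the 2.5–5 Å contact window,
  giving connected networks and a buried ligand that touches every
  residue. Radii packing strands closer than 2 Å are rejected.
- **Elastic-network ensembles.** The anisotropic (3N) network model:
  uniform springs within a 12 Å cutoff, covariance kT·H⁺. The anisotropic
  variant is used so sampled ensembles have directional correlations like
  real MD. Near-zero modes are removed by eigenvalue truncation at
  1e-8 relative to the largest eigenvalue — a threshold rather than a
  fixed count of six, because degenerate geometries (e.g. the two-body
  single-spring system, which has five rigid modes) are legitimate test
  cases. Disconnected networks are rejected with the component sizes
  named. Defaults kT = 0.1, γ = 1 give Cα RMSF of ~0.3–0.5 Å on the toy
  barrel, a realistic folded-core scale.
- **Portal-coupling covariance.** A designed low-rank-plus-noise
  covariance: one collective coordinate moves a "portal" block and a
  "β5-β6" block in opposite directions (coupled, wild-type-like), or each
  block rides its own independent mode (decoupled, mutant-like). Loadings
  are projected onto the complement of the six rigid-body modes of the
  mean structure, and the decoupled block modes use zero-mean stretch
  profiles — otherwise the superposition step folds the blocks' net
  translation into spurious anti-correlations of order −0.1. Defaults
  (collective SD 1.0, isotropic noise SD 0.4 Å per axis) give a coupled
  cross-block correlation near −0.6 and a decoupled one near 0.
- **Two-state opening series.** A hidden Markov chain (closed 8 Å, open
  16 Å, p(close→open) = 0.02, p(open→close) = 0.08 per frame → stationary
  open fraction 0.2, emission noise σ = 0.5 Å), started in its stationary
  distribution so label fractions are unbiased. The relaxation time
  (10 frames) makes the 10⁴-frame fraction estimate accurate to ~0.02 SD.
- **Binding curves.** The one-site model over an 11-point 0.1–15 μM
  ladder emulating an SPR dilution series, with the published wild-type
  (B_max 1466 R.U., K_d 3.1 μM) and F57A (1408 R.U., 6.2 μM) rows as
  generating truth and optional Gaussian noise (2 % of B_max in the noisy
  scenario).

What passing on these generators does **not** show: Gaussian ensembles
have no anharmonicity, no ligand–protein coupling and no actual barrel
opening, so they validate the estimators, not the biology; the two-state
series has no intermediate states or drifting baselines; the toy barrel's
contact network is far more regular than a real protein's; binding noise
is homoscedastic whereas instrument noise often is not. Conclusions about
real trajectories require rerunning the same operators on real data.

## Problem sizes and determinism

The analysis scripts use 4000–5000-frame ensembles over 60 residues,
10⁴-frame opening series, and 200-replicate binding sweeps — sizes at
which the closed-loop checks (estimated vs analytic DCCM ≤ 0.05 max-abs;
fraction recovery within a few percent) are comfortably resolved while
the whole study runs in well under a minute. All stochastic stages take
explicit seeds and record them, with parameters, in their outputs; rerun
with the same seed, every table is byte-identical.
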
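"""Synthetic inputs with known ground truth for every pipeline stage.

Real inputs for this kind of study are microsecond atomistic MD
trajectories, crystal structures, and SPR concentration series.  The
generators here emulate the *statistical shape* of those inputs at desk
scale, with analytically known answers:

- a toy β-barrel (Cα/Cβ pseudo-residues on a cylinder, optional linear
  ligand along the axis) for contact-network and selection tests;
- Gaussian coordinate ensembles drawn from an anisotropic elastic-network
  covariance, whose exact cross-correlation map is computable from the
  generating covariance;
- a designed two-block "portal coupling" covariance whose cross-block
  anti-correlation can be switched on (wild-type-like coordinated
  open/close motion) or off (mutant-like decoupled motion);
- a hidden two-state Markov distance series for barrel-opening detection;
- one-site binding curves with optional Gaussian noise.

Every generator is deterministic given (parameters, seed) and records both
in the output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import ConnectivityError, NumericError, ParameterError
from .geometry import DistanceSeries
from .binding_fit import BindingDataset, one_site_response
from .structure_io import Atom, Structure, Trajectory

_RESNAME_CYCLE = ["VAL", "LEU", "ILE", "THR", "SER", "PHE"]


@dataclass
class EnsembleSpec:
    """Parameters of an elastic-network Gaussian ensemble."""

    cutoff: float = 12.0        # Å
    spring: float = 1.0         # energy/Å²
    kT: float = 0.1             # same energy units
    n_frames: int = 5000
    seed: int = 0

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ParameterError("cutoff must be positive")
        if self.n_frames < 2:
            raise ParameterError("need at least 2 frames")


@dataclass
class OpeningSpec:
    """Two-state (closed/open) hidden-Markov distance series parameters."""

    d_closed: float = 8.0       # Å
    d_open: float = 16.0        # Å
    p_open: float = 0.02        # per-frame P(closed→open)
    p_close: float = 0.08       # per-frame P(open→closed)
    noise_sd: float = 0.5       # Å
    n_frames: int = 10000
    seed: int = 0

    def __post_init__(self):
        if self.d_open <= self.d_closed:
            raise ParameterError("d_open must exceed d_closed")
        for p in (self.p_open, self.p_close):
            if not (0.0 < p < 1.0):
                raise ParameterError("transition probabilities must be in (0,1)")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be ≥ 0")

    @property
    def stationary_open_fraction(self) -> float:
        return self.p_open / (self.p_open + self.p_close)


def build_toy_barrel(n_strands: int = 10,
                     residues_per_strand: int = 6,
                     radius: float = 4.8,
                     rise: float = 3.3,
                     with_ligand: bool = False) -> Structure:
    """Idealized β-barrel of Cα/Cβ pseudo-residues on a cylinder.

    Strands alternate direction (antiparallel); Cβ atoms point radially
    outward.  ``with_ligand`` adds a linear 16-carbon hetero chain along the
    barrel axis (a palmitate stand-in).  The default radius is chosen so
    that neighbouring strands — and the axial ligand — sit inside a typical
    2.5–5 Å heavy-atom contact window: the pseudo-residues carry no side
    chains, so the cylinder is proportionally tighter than a real barrel.
    Deterministic for fixed parameters.  Raises :class:`ParameterError` when
    the radius packs neighbouring strands closer than 2.0 Å (clashes).
    """
    if n_strands < 3:
        raise ParameterError("need at least 3 strands")
    strand_gap = 2.0 * radius * np.sin(np.pi / n_strands)
    if strand_gap < 2.0:
        raise ParameterError(
            f"radius {radius} Å packs neighbouring strands {strand_gap:.2f} Å apart (< 2 Å)")
    atoms: list[Atom] = []
    serial = 1
    resid = 0
    for s in range(n_strands):
        angle = 2.0 * np.pi * s / n_strands
        ux, uy = np.cos(angle), np.sin(angle)
        down = s % 2 == 1  # antiparallel alternation
        for k in range(residues_per_strand):
            resid += 1
            kk = residues_per_strand - 1 - k if down else k
            z = kk * rise
            # slight stagger between strands mimics β-sheet registry
            z += 0.5 * rise * (s % 2)
            ca = (radius * ux, radius * uy, z)
            cb = ((radius + 1.53) * ux, (radius + 1.53) * uy, z)
            resname = _RESNAME_CYCLE[resid % len(_RESNAME_CYCLE)]
            atoms.append(Atom(serial=serial, name="CA", element="C", resname=resname,
                              chain="A", resid=resid, coords=ca))
            serial += 1
            atoms.append(Atom(serial=serial, name="CB", element="C", resname=resname,
                              chain="A", resid=resid, coords=cb))
            serial += 1
    if with_ligand:
        z0 = 0.5 * (residues_per_strand - 1) * rise - 0.65 * 15
        for j in range(16):
            atoms.append(Atom(serial=serial, name=f"C{j + 1}", element="C",
                              resname="PLM", chain="A", resid=201,
                              coords=(0.0, 0.0, z0 + 1.3 * j), is_hetero=True))
            serial += 1
    return Structure(atoms=atoms, model_id=1)


def _calpha_coords(structure: Structure) -> tuple[np.ndarray, list[int]]:
    idx = [i for i, a in enumerate(structure.atoms)
           if a.name == "CA" and not a.is_hetero]
    coords = np.array([structure.atoms[i].coords for i in idx], dtype=float)
    return coords, idx


def enm_covariance(structure: Structure,
                   cutoff: float = 12.0,
                   spring: float = 1.0,
                   kT: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Anisotropic elastic-network covariance and its analytic DCCM.

    Builds the 3N×3N network Hessian on Cα atoms (uniform spring γ for
    pairs within ``cutoff``), removes the near-zero rigid-body modes by
    eigenvalue truncation (threshold 1e-8 relative to the largest
    eigenvalue), and returns

        covariance = kT · H⁺   (3N×3N)

    together with the N×N cross-correlation map computed from the trace of
    the per-residue 3×3 covariance blocks — the same formula the estimator
    applies to sampled ensembles.  Raises :class:`ConnectivityError` when
    the contact graph is disconnected at the cutoff.
    """
    coords, _ = _calpha_coords(structure)
    n = len(coords)
    if n < 2:
        raise ParameterError("need at least 2 Cα atoms")
    dmat = squareform(pdist(coords))
    contact = (dmat <= cutoff) & ~np.eye(n, dtype=bool)
    # connectivity check
    from scipy.sparse.csgraph import connected_components
    n_comp, labels = connected_components(contact, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        raise ConnectivityError(
            f"elastic network disconnected at cutoff {cutoff} Å: "
            f"{n_comp} components of sizes {sizes.tolist()}")
    H = np.zeros((3 * n, 3 * n))
    for i in range(n):
        for j in range(i + 1, n):
            if not contact[i, j]:
                continue
            d = coords[j] - coords[i]
            k33 = spring * np.outer(d, d) / (d @ d)
            H[3 * i:3 * i + 3, 3 * j:3 * j + 3] -= k33
            H[3 * j:3 * j + 3, 3 * i:3 * i + 3] -= k33
            H[3 * i:3 * i + 3, 3 * i:3 * i + 3] += k33
            H[3 * j:3 * j + 3, 3 * j:3 * j + 3] += k33
    evals, evecs = np.linalg.eigh(H)
    thresh = 1e-8 * evals[-1]
    keep = evals > thresh
    inv = np.zeros_like(evals)
    inv[keep] = 1.0 / evals[keep]
    cov = kT * (evecs * inv) @ evecs.T
    return cov, analytic_dccm(cov)


def analytic_dccm(covariance: np.ndarray) -> np.ndarray:
    """Cross-correlation map implied by a 3N×3N coordinate covariance."""
    m = covariance.shape[0]
    if m % 3 != 0 or covariance.shape[1] != m:
        raise ParameterError("covariance must be 3N×3N")
    n = m // 3
    blocks = covariance.reshape(n, 3, n, 3)
    tr = np.einsum("iaja->ij", blocks)  # trace of each 3×3 block
    var = np.diag(tr)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = tr / np.sqrt(np.outer(var, var))
    C = np.clip(C, -1.0, 1.0)
    C = 0.5 * (C + C.T)
    np.fill_diagonal(C, 1.0)
    return C


def _rigid_mode_projector(coords: np.ndarray) -> np.ndarray:
    """Projector onto the orthogonal complement of the 6 rigid-body modes."""
    n = coords.shape[0]
    centered = coords - coords.mean(axis=0)
    basis = []
    for axis in np.eye(3):  # translations
        v = np.tile(axis, n)
        basis.append(v)
    for axis in np.eye(3):  # infinitesimal rotations about the centroid
        v = np.cross(np.tile(axis, (n, 1)), centered).ravel()
        basis.append(v)
    B = np.array(basis).T  # 3n × 6
    Q, _ = np.linalg.qr(B)
    return np.eye(3 * n) - Q @ Q.T


def portal_coupling_covariance(mean_coords: np.ndarray,
                               block_a: list[int],
                               block_b: list[int],
                               coupled: bool = True,
                               collective_sd: float = 1.0,
                               noise_sd: float = 0.4) -> tuple[np.ndarray, np.ndarray]:
    """Designed covariance with tunable anti-correlation between two blocks.

    Emulates the coordinated open/close breathing seen in wild-type portal
    regions: when ``coupled``, one collective coordinate moves block A and
    block B in opposite directions, producing a strong negative cross-block
    correlation (approximately −collective_sd² / (collective_sd² + 3·noise_sd²));
    when decoupled (mutant-like), each block rides its own independent
    collective coordinate along orthogonal directions and the cross-block
    correlation is near 0.  The collective loading vectors are projected
    onto the complement of the 6 rigid-body modes of ``mean_coords`` — as
    with the elastic-network covariance, the designed motion is purely
    internal, so superposing sampled frames does not fold block motion into
    spurious correlations.  Block indices are 0-based residue positions.
    Returns (3N×3N covariance, analytic DCCM).
    """
    mean = np.asarray(mean_coords, dtype=float)
    n_residues = mean.shape[0]
    if set(block_a) & set(block_b):
        raise ParameterError("blocks must be disjoint")
    for idx in (*block_a, *block_b):
        if not (0 <= idx < n_residues):
            raise ParameterError(f"residue index {idx} outside 0..{n_residues - 1}")
    ux = np.array([1.0, 0.0, 0.0])
    uy = np.array([0.0, 1.0, 0.0])
    m = 3 * n_residues
    if coupled:
        L = np.zeros((m, 1))
        for i in block_a:
            L[3 * i:3 * i + 3, 0] = collective_sd * ux
        for i in block_b:
            L[3 * i:3 * i + 3, 0] = -collective_sd * ux
    else:
        # independent per-block stretch modes: amplitude varies linearly
        # across the block with zero mean, so neither mode carries net
        # translation that the rigid projection would smear across blocks
        L = np.zeros((m, 2))
        for col, (block, u) in enumerate(((block_a, ux), (block_b, uy))):
            w = np.arange(len(block), dtype=float)
            w -= w.mean()
            w *= np.sqrt(len(block)) / np.linalg.norm(w)
            for wk, i in zip(w, sorted(block)):
                L[3 * i:3 * i + 3, col] = collective_sd * wk * u
    P = _rigid_mode_projector(mean)
    L = P @ L
    cov = L @ L.T + noise_sd ** 2 * np.eye(m)
    return cov, analytic_dccm(cov)


def sample_ensemble(mean_coords: np.ndarray,
                    covariance: np.ndarray,
                    n_frames: int,
                    seed: int,
                    topology: list[Atom] | None = None) -> Trajectory:
    """Draw frames from N(mean, covariance); reproducible per seed.

    ``covariance`` is 3N×3N over the N atoms of ``mean_coords``.  Eigenvalues
    below −1e-8·λmax raise :class:`NumericError`; small negatives are
    clipped to zero.
    """
    mean = np.asarray(mean_coords, dtype=float)
    n = mean.shape[0]
    if covariance.shape != (3 * n, 3 * n):
        raise ParameterError(f"covariance must be {3 * n}×{3 * n}")
    evals, evecs = np.linalg.eigh(covariance)
    lmax = max(evals[-1], 0.0)
    if evals[0] < -1e-8 * max(lmax, 1.0):
        raise NumericError(f"covariance not PSD: min eigenvalue {evals[0]:.3e}")
    evals = np.clip(evals, 0.0, None)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_frames, 3 * n))
    disp = z @ (evecs * np.sqrt(evals)).T
    frames = mean[None, :, :] + disp.reshape(n_frames, n, 3)
    if topology is None:
        topology = [Atom(serial=i + 1, name="CA", element="C",
                         resname=_RESNAME_CYCLE[(i + 1) % len(_RESNAME_CYCLE)],
                         chain="A", resid=i + 1, coords=tuple(mean[i]))
                    for i in range(n)]
    return Trajectory(topology=topology, frames=frames,
                      metadata={"generator": "sample_ensemble", "seed": seed,
                                "n_frames": n_frames})


def ensemble_from_structure(structure: Structure,
                            spec: EnsembleSpec) -> tuple[Trajectory, np.ndarray]:
    """Elastic-network ensemble of a structure's Cα atoms.

    Returns (trajectory, analytic DCCM).  Convenience wrapper chaining
    :func:`enm_covariance` and :func:`sample_ensemble`.
    """
    coords, idx = _calpha_coords(structure)
    cov, C = enm_covariance(structure, cutoff=spec.cutoff,
                            spring=spec.spring, kT=spec.kT)
    topo = [structure.atoms[i] for i in idx]
    traj = sample_ensemble(coords, cov, spec.n_frames, spec.seed, topology=topo)
    traj.metadata.update({"generator": "enm_ensemble", "cutoff": spec.cutoff,
                          "spring": spec.spring, "kT": spec.kT})
    return traj, C


def simulate_opening(spec: OpeningSpec) -> tuple[DistanceSeries, np.ndarray]:
    """Two-state hidden-Markov distance series plus the true state labels.

    State 0 emits around the closed distance, state 1 around the open one;
    emission noise is Gaussian.  The chain starts in its stationary
    distribution so the label fraction is unbiased.
    """
    rng = np.random.default_rng(spec.seed)
    labels = np.empty(spec.n_frames, dtype=np.int8)
    state = 1 if rng.random() < spec.stationary_open_fraction else 0
    for t in range(spec.n_frames):
        labels[t] = state
        if state == 0 and rng.random() < spec.p_open:
            state = 1
        elif state == 1 and rng.random() < spec.p_close:
            state = 0
    levels = np.where(labels == 1, spec.d_open, spec.d_closed)
    distances = levels + spec.noise_sd * rng.standard_normal(spec.n_frames)
    distances = np.maximum(distances, 1e-6)  # physical distances stay positive
    series = DistanceSeries(
        frame_indices=np.arange(spec.n_frames),
        distances=distances,
        descriptor={"generator": "two_state_markov", "seed": spec.seed,
                    "d_closed": spec.d_closed, "d_open": spec.d_open,
                    "p_open": spec.p_open, "p_close": spec.p_close,
                    "noise_sd": spec.noise_sd,
                    "stationary_open_fraction": spec.stationary_open_fraction},
    )
    return series, labels


def simulate_binding(concentrations,
                     bmax: float,
                     kd: float,
                     noise_sd: float = 0.0,
                     seed: int = 0) -> BindingDataset:
    """One-site binding responses with optional Gaussian noise (R.U.)."""
    if noise_sd < 0:
        raise ParameterError("noise_sd must be ≥ 0")
    conc = np.asarray(concentrations, dtype=float)
    y = one_site_response(conc, bmax, kd)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + noise_sd * rng.standard_normal(conc.shape)
    return BindingDataset(concentrations=conc, responses=np.asarray(y, dtype=float),
                          metadata={"generator": "one_site", "Bmax": bmax, "Kd": kd,
                                    "noise_sd": noise_sd, "seed": seed})


#: SPR concentration series emulating a 0.1–15 μM dilution ladder.
DEFAULT_SPR_CONCENTRATIONS = np.array(
    [0.1, 0.2, 0.4, 0.8, 1.5, 3.0, 5.0, 7.5, 10.0, 12.5, 15.0])
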
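"""Per-residue fluctuation statistics: RMSF, dynamic cross-correlation maps,
and portal-region segment correlation comparisons.

The cross-correlation map uses the isotropic scalar-product definition

    C_ij = ⟨Δr_i·Δr_j⟩ / sqrt(⟨|Δr_i|²⟩ ⟨|Δr_j|²⟩),   Δr_i = r_i(t) − ⟨r_i⟩,

computed on Cα positions about the ensemble mean (not the first frame).
Entries lie in [−1, 1]; +1 is fully correlated motion, −1 fully
anti-correlated.  Residues that do not move at all have no defined
correlation and are flagged as missing (NaN) rather than silently zeroed.

Segment statistics summarize blocks of the map between named regions —
typically the lid helices and the two portal loops — and the wt-vs-mutant
comparison quantifies loss of anti-correlation as a positive shift in the
block mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (ComparisonError, ConfigError, DegenerateDataError,
                     InsufficientFramesError, ParameterError)
from .structure_io import Selection, Structure, Trajectory, select
from .superpose import AlignedTrajectory

#: Default portal-region segment ranges (inclusive resid ranges).  These are
#: configuration defaults for a P2-like FABP topology, not constants; every
#: report echoes the ranges actually used.
DEFAULT_SEGMENTS = {
    "alpha1": (14, 22),
    "alpha2": (26, 34),
    "loop_b3b4": (55, 60),
    "loop_b5b6": (74, 79),
}

DEFAULT_ANTICORR_THRESHOLD = -0.3
#: Fraction of frames discarded as equilibration (0.5 μs of a 3 μs run).
DEFAULT_EQUILIBRATION_FRACTION = 1.0 / 6.0


@dataclass
class RMSFProfile:
    resids: np.ndarray
    rmsf: np.ndarray  # Å

    def to_csv(self) -> str:
        lines = ["resid,rmsf_A"]
        lines += [f"{r},{v:.6f}" for r, v in zip(self.resids, self.rmsf)]
        return "\n".join(lines) + "\n"


@dataclass
class DCCMatrix:
    resids: np.ndarray
    C: np.ndarray

    def __post_init__(self):
        self.resids = np.asarray(self.resids)
        self.C = np.asarray(self.C, dtype=float)

    @property
    def missing(self) -> np.ndarray:
        """Boolean mask of residues with undefined correlations."""
        return np.isnan(np.diag(self.C))

    def to_csv(self) -> str:
        head = "resid," + ",".join(str(r) for r in self.resids)
        lines = [head]
        for r, row in zip(self.resids, self.C):
            lines.append(str(r) + "," + ",".join(f"{v:.6f}" for v in row))
        return "\n".join(lines) + "\n"


@dataclass
class SegmentSet:
    """Named inclusive residue ranges (helices, loops, user segments)."""

    segments: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_SEGMENTS))

    def __post_init__(self):
        for name, (lo, hi) in self.segments.items():
            if hi < lo:
                raise ConfigError(f"segment {name!r}: empty range {lo}–{hi}")

    def resids(self, name: str) -> list[int]:
        if name not in self.segments:
            raise ConfigError(
                f"unknown segment {name!r}; defined: {sorted(self.segments)}")
        lo, hi = self.segments[name]
        return list(range(lo, hi + 1))


@dataclass
class SegmentCorrelation:
    segment_a: str
    segment_b: str
    mean: float
    min: float
    max: float
    count_below_threshold: int
    n_pairs: int
    anticorr_threshold: float
    ranges: dict[str, tuple[int, int]] = field(default_factory=dict)


@dataclass
class AntiCorrelationDelta:
    """wt → mutant change in a segment-pair correlation block.

    A positive ``delta_mean`` on an anti-correlated block means the mutant
    has lost anti-correlation relative to the reference.
    """

    segment_a: str
    segment_b: str
    mean_reference: float
    mean_variant: float
    delta_mean: float
    delta_count: int


def _calpha_view(aligned: AlignedTrajectory, selection: Selection | None):
    traj = aligned.trajectory
    if selection is None:
        selection = Selection.calpha()
    probe = Structure(atoms=traj.topology, model_id=0)
    idx = select(probe, selection)
    if not idx:
        raise DegenerateDataError("selection resolves to no atoms")
    resids = np.array([traj.topology[i].resid for i in idx])
    return traj.frames[:, idx, :], resids


def rmsf(aligned: AlignedTrajectory, selection: Selection | None = None) -> RMSFProfile:
    """Root mean-square fluctuation about the mean position, per residue (Å)."""
    X, resids = _calpha_view(aligned, selection)
    if X.shape[0] < 2:
        raise InsufficientFramesError("RMSF needs at least 2 frames")
    d = X - X.mean(axis=0)
    vals = np.sqrt((d ** 2).sum(axis=2).mean(axis=0))
    return RMSFProfile(resids=resids, rmsf=vals)


def dccm(aligned: AlignedTrajectory, selection: Selection | None = None) -> DCCMatrix:
    """Dynamic cross-correlation map over the selected Cα set."""
    X, resids = _calpha_view(aligned, selection)
    F = X.shape[0]
    if F < 2:
        raise InsufficientFramesError("DCCM needs at least 2 frames")
    D = X - X.mean(axis=0)
    M = np.einsum("fid,fjd->ij", D, D) / F
    var = np.diag(M).copy()
    # relative floor: a residue whose variance is at roundoff level relative
    # to the most mobile one has no defined correlation
    zero = var <= 1e-12 * max(float(var.max()), 1e-300)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = M / np.sqrt(np.outer(var, var))
    C = np.clip(C, -1.0, 1.0)
    C = 0.5 * (C + C.T)
    np.fill_diagonal(C, 1.0)
    if zero.any():
        C[zero, :] = np.nan
        C[:, zero] = np.nan
    return DCCMatrix(resids=resids, C=C)


def covariance_rmsf_consistency(aligned: AlignedTrajectory,
                                selection: Selection | None = None) -> float:
    """Max |rmsf² − tr(per-residue covariance block)| — internal check."""
    X, _ = _calpha_view(aligned, selection)
    D = X - X.mean(axis=0)
    trace = (D ** 2).sum(axis=2).mean(axis=0)
    prof = rmsf(aligned, selection)
    return float(np.max(np.abs(prof.rmsf ** 2 - trace)))


def segment_correlation(dccmatrix: DCCMatrix,
                        segments: SegmentSet,
                        pair: tuple[str, str],
                        anticorr_threshold: float = DEFAULT_ANTICORR_THRESHOLD,
                        ) -> SegmentCorrelation:
    """Statistics of the correlation block between two named segments.

    Self-pairs (i == j) are excluded when the segments overlap.
    """
    name_a, name_b = pair
    res_a = set(segments.resids(name_a))
    res_b = set(segments.resids(name_b))
    pos = {r: k for k, r in enumerate(dccmatrix.resids)}
    ia = [pos[r] for r in sorted(res_a) if r in pos]
    ib = [pos[r] for r in sorted(res_b) if r in pos]
    if not ia or not ib:
        raise DegenerateDataError(
            f"segment pair ({name_a}, {name_b}) resolves to an empty block in the map")
    vals = [dccmatrix.C[i, j] for i in ia for j in ib if i != j]
    vals = [v for v in vals if not np.isnan(v)]
    if not vals:
        raise DegenerateDataError(
            f"segment pair ({name_a}, {name_b}): no off-diagonal pairs")
    arr = np.array(vals)
    return SegmentCorrelation(
        segment_a=name_a, segment_b=name_b,
        mean=float(arr.mean()), min=float(arr.min()), max=float(arr.max()),
        count_below_threshold=int((arr <= anticorr_threshold).sum()),
        n_pairs=len(arr), anticorr_threshold=anticorr_threshold,
        ranges={name_a: segments.segments[name_a], name_b: segments.segments[name_b]},
    )


def anticorrelation_loss(corr_reference: SegmentCorrelation,
                         corr_variant: SegmentCorrelation) -> AntiCorrelationDelta:
    """Change in block correlation between a reference and a variant map."""
    if ((corr_reference.segment_a, corr_reference.segment_b)
            != (corr_variant.segment_a, corr_variant.segment_b)):
        raise ComparisonError(
            f"segment pairs differ: ({corr_reference.segment_a}, {corr_reference.segment_b}) "
            f"vs ({corr_variant.segment_a}, {corr_variant.segment_b})")
    return AntiCorrelationDelta(
        segment_a=corr_reference.segment_a, segment_b=corr_reference.segment_b,
        mean_reference=corr_reference.mean, mean_variant=corr_variant.mean,
        delta_mean=corr_variant.mean - corr_reference.mean,
        delta_count=corr_variant.count_below_threshold - corr_reference.count_below_threshold,
    )


def discard_equilibration(traj: Trajectory,
                          fraction: float | None = None,
                          time_ns: float | None = None) -> Trajectory:
    """Drop the initial equilibration portion of a trajectory.

    By default the first sixth of the frames is discarded, mirroring the
    convention of analysing the last 2.5 μs of a 3 μs production run.
    ``time_ns`` cuts at an absolute time instead when frame times are known.
    """
    if time_ns is not None:
        if traj.frame_times is None:
            raise ParameterError("time-based cut requires frame_times")
        keep = traj.frame_times >= time_ns
        frames = traj.frames[keep]
        times = traj.frame_times[keep]
    else:
        if fraction is None:
            fraction = DEFAULT_EQUILIBRATION_FRACTION
        if not (0.0 <= fraction < 1.0):
            raise ParameterError(f"fraction must be in [0, 1), got {fraction}")
        cut = int(round(traj.n_frames * fraction))
        frames = traj.frames[cut:]
        times = traj.frame_times[cut:] if traj.frame_times is not None else None
    if frames.shape[0] < 2:
        raise InsufficientFramesError("equilibration cut leaves fewer than 2 frames")
    return Trajectory(topology=traj.topology, frames=frames.copy(),
                      frame_times=times, metadata=dict(traj.metadata))
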
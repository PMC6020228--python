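"""Rigid-body least-squares superposition and trajectory alignment.

Superposition uses the closed-form SVD solution (Kabsch) with the usual
determinant sign correction, so an improper rotation (reflection) is never
returned.  Unit weights throughout: fitting is done on Cα subsets where
mass weighting is immaterial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateGeometryError, SelectionError
from .structure_io import Selection, Trajectory, select, Structure

_DEG_TOL = 1e-10


@dataclass(frozen=True)
class RigidTransform:
    """x ↦ R·x + t with R a proper rotation (det = +1)."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(rotation=np.eye(3), translation=np.zeros(3))


@dataclass
class AlignedTrajectory:
    """A trajectory after per-frame best-fit superposition onto a reference."""

    trajectory: Trajectory
    fit_indices: list[int]
    reference: np.ndarray  # coordinates of the fit atoms
    per_frame_rmsd: np.ndarray
    reference_mode: str = "iterative-mean"
    metadata: dict = field(default_factory=dict)


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[RigidTransform, float]:
    """Optimal rigid transform mapping ``mobile`` onto ``reference``.

    Returns the transform and the minimum RMSD (Å).  Requires ≥3
    non-collinear point pairs.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise DegenerateGeometryError(f"point sets must be M×3 and congruent, got {P.shape} vs {Q.shape}")
    m = P.shape[0]
    if m < 3:
        raise DegenerateGeometryError(f"need at least 3 point pairs, got {m}")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    # collinearity check on either set: second singular value ≈ 0
    for X in (P0, Q0):
        sv = np.linalg.svd(X, compute_uv=False)
        if sv[1] <= _DEG_TOL * max(sv[0], 1.0):
            raise DegenerateGeometryError("point set is (near-)collinear; rotation underdetermined")
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    # residual computed directly: numerically exact near rmsd = 0 where the
    # trace identity suffers catastrophic cancellation
    resid = P0 @ R.T - Q0
    rmsd = float(np.sqrt((resid * resid).sum() / m))
    return RigidTransform(rotation=R, translation=t), rmsd


def _resolve_fit_indices(traj: Trajectory, fit_selection: Selection | None) -> list[int]:
    if fit_selection is None:
        fit_selection = Selection.calpha()
    probe = Structure(atoms=traj.topology, model_id=0)
    idx = select(probe, fit_selection)
    if len(idx) < 3:
        raise SelectionError(f"fit selection resolves to {len(idx)} atoms; need ≥3")
    return idx


def _canonical_transform(ref: np.ndarray) -> RigidTransform:
    """Deterministic pose for a reference point set.

    Centroid goes to the origin; the first well-conditioned atom direction
    becomes +x and the next one fixes the xy-plane, with a proper rotation
    completing the frame.  Rigid-invariant by construction: applying any
    rigid transform to ``ref`` yields the same canonical pose.
    """
    c = ref.mean(axis=0)
    centered = ref - c
    e1 = None
    e2 = None
    for v in centered:
        n = np.linalg.norm(v)
        if n < 1e-8:
            continue
        if e1 is None:
            e1 = v / n
            continue
        w = v - (v @ e1) * e1
        wn = np.linalg.norm(w)
        if wn > 1e-6 * n:
            e2 = w / wn
            break
    if e1 is None or e2 is None:
        raise DegenerateGeometryError("reference geometry is degenerate")
    e3 = np.cross(e1, e2)
    R = np.stack([e1, e2, e3])  # rows: maps e1→x, e2→y, e3→z
    return RigidTransform(rotation=R, translation=-R @ c)


def align_trajectory(traj: Trajectory,
                     fit_selection: Selection | None = None,
                     reference_mode: str = "iterative-mean",
                     max_iter: int = 10,
                     tol: float = 1e-6) -> AlignedTrajectory:
    """Superpose every frame onto a common reference.

    Each frame gets its own best-fit transform computed on the fit atoms and
    applied to all atoms.  ``reference_mode``:

    - ``"iterative-mean"`` (default): start from the first frame, then
      iterate aligning to the mean fit-atom structure until the mean moves
      by < ``tol`` Å RMSD or ``max_iter`` rounds.
    - ``"first-frame"``: single pass onto frame 0.
    """
    if reference_mode not in ("iterative-mean", "first-frame"):
        raise ValueError(f"unknown reference_mode {reference_mode!r}")
    idx = _resolve_fit_indices(traj, fit_selection)
    frames = traj.frames.copy()
    ref = frames[0, idx].copy()

    def _pass(frames: np.ndarray, ref: np.ndarray) -> np.ndarray:
        rmsds = np.empty(frames.shape[0])
        for f in range(frames.shape[0]):
            tr, rmsd = kabsch(frames[f, idx], ref)
            frames[f] = tr.apply(frames[f])
            rmsds[f] = rmsd
        return rmsds

    rmsds = _pass(frames, ref)
    if reference_mode == "iterative-mean":
        for _ in range(max_iter):
            new_ref = frames[:, idx].mean(axis=0)
            shift = float(np.sqrt(((new_ref - ref) ** 2).sum(axis=1).mean()))
            ref = new_ref
            rmsds = _pass(frames, ref)
            if shift < tol:
                break
    # canonical output frame: the result must not depend on how the input
    # trajectory happened to be positioned, so the reference is moved to a
    # deterministic pose (centroid at origin, orientation from a
    # Gram-Schmidt frame over the reference geometry)
    canon = _canonical_transform(ref)
    ref = canon.apply(ref)
    frames = canon.apply(frames.reshape(-1, 3)).reshape(frames.shape)
    aligned = Trajectory(topology=traj.topology, frames=frames,
                         frame_times=traj.frame_times,
                         metadata=dict(traj.metadata))
    return AlignedTrajectory(trajectory=aligned, fit_indices=idx, reference=ref,
                             per_frame_rmsd=rmsds, reference_mode=reference_mode)
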
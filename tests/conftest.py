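import numpy as np
import pytest

from portalwatch.structure_io import Atom, Structure, Trajectory
from portalwatch.superpose import AlignedTrajectory
from portalwatch.synthetic_data import build_toy_barrel


@pytest.fixture(scope="session")
def toy_barrel():
    return build_toy_barrel()


@pytest.fixture(scope="session")
def toy_barrel_ligand():
    return build_toy_barrel(with_ligand=True)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_atoms(coords, names=None, resids=None, resnames=None, hetero=None):
    """Minimal atom list over coordinate rows (defaults: one CA per residue)."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    names = names or ["CA"] * n
    resids = resids or list(range(1, n + 1))
    resnames = resnames or ["ALA"] * n
    hetero = hetero or [False] * n
    return [
        Atom(serial=i + 1, name=names[i], element=names[i][0], resname=resnames[i],
             chain="A", resid=resids[i], coords=tuple(coords[i]), is_hetero=hetero[i])
        for i in range(n)
    ]


def make_trajectory(frames, **atom_kwargs) -> Trajectory:
    frames = np.asarray(frames, dtype=float)
    topo = make_atoms(frames[0], **atom_kwargs)
    return Trajectory(topology=topo, frames=frames)


def wrap_aligned(traj: Trajectory) -> AlignedTrajectory:
    """Treat a trajectory as already aligned (identity superposition)."""
    return AlignedTrajectory(
        trajectory=traj,
        fit_indices=list(range(traj.n_atoms)),
        reference=traj.frames.mean(axis=0),
        per_frame_rmsd=np.zeros(traj.n_frames),
        reference_mode="pre-aligned",
    )
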
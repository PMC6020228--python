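"""Distance time series and β-barrel opening detection.

Distances are computed on raw (unaligned) coordinates — inter-group
distances are invariant under rigid motion of a whole frame, so this module
does not depend on superposition.  Opening events are maximal runs of
frames whose loop-tip distance exceeds a threshold for at least a dwell
time, the operational definition used to flag barrel-opening excursions in
a distance trace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ParameterError, SelectionError
from .structure_io import BACKBONE_NAMES, Selection, Structure, Trajectory, select

logger = logging.getLogger(__name__)

DEFAULT_OPENING_THRESHOLD = 13.0  # Å
DEFAULT_MIN_DWELL = 10  # frames

#: Default loop-tip residues for a P2-like FABP (configurable, echoed in reports).
DEFAULT_LOOP_TIPS = {"loop_b3b4": 57, "loop_b5b6": 77}


@dataclass
class DistanceSeries:
    frame_indices: np.ndarray
    distances: np.ndarray  # Å
    descriptor: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.distances)

    def to_csv(self) -> str:
        lines = ["frame,distance_A"]
        lines += [f"{f},{d:.6f}" for f, d in zip(self.frame_indices, self.distances)]
        return "\n".join(lines) + "\n"


@dataclass
class OpeningEvents:
    threshold: float
    min_dwell: int
    events: list[tuple[int, int]]  # inclusive (start_frame, end_frame)
    fraction_open: float
    n_frames: int


def _group_indices(traj: Trajectory, selection: Selection, label: str) -> list[int]:
    probe = Structure(atoms=traj.topology, model_id=0)
    idx = select(probe, selection)
    if not idx:
        raise SelectionError(f"group {label} selects no atoms in the topology")
    return idx


def distance_series(traj: Trajectory,
                    group_a: Selection,
                    group_b: Selection,
                    mode: str = "calpha") -> DistanceSeries:
    """Per-frame distance between two atom groups.

    ``mode``:
      - ``"calpha"``: the single Cα of each group (error if not exactly one);
      - ``"centroid"``: unweighted centroid of each group's selected atoms;
      - ``"min-heavy"``: minimum heavy-atom pair distance between the groups.
    """
    if mode not in ("calpha", "centroid", "min-heavy"):
        raise ParameterError(f"unknown distance mode {mode!r}")
    ia = _group_indices(traj, group_a, "A")
    ib = _group_indices(traj, group_b, "B")
    topo = traj.topology
    if mode == "calpha":
        ia = [i for i in ia if topo[i].name == "CA"]
        ib = [i for i in ib if topo[i].name == "CA"]
        if len(ia) != 1 or len(ib) != 1:
            raise SelectionError(
                f"calpha mode needs exactly one CA per group (got {len(ia)} and {len(ib)})")
        d = np.linalg.norm(traj.frames[:, ia[0]] - traj.frames[:, ib[0]], axis=1)
    elif mode == "centroid":
        ca = traj.frames[:, ia, :].mean(axis=1)
        cb = traj.frames[:, ib, :].mean(axis=1)
        d = np.linalg.norm(ca - cb, axis=1)
    else:  # min-heavy
        ia = [i for i in ia if not topo[i].is_hydrogen]
        ib = [i for i in ib if not topo[i].is_hydrogen]
        if not ia or not ib:
            raise SelectionError("min-heavy mode: a group has no heavy atoms")
        d = np.empty(traj.n_frames)
        for f in range(traj.n_frames):
            d[f] = cdist(traj.frames[f, ia], traj.frames[f, ib]).min()
    return DistanceSeries(
        frame_indices=np.arange(traj.n_frames),
        distances=d,
        descriptor={"mode": mode, "n_atoms_a": len(ia), "n_atoms_b": len(ib)},
    )


def detect_opening(series: DistanceSeries,
                   threshold: float = DEFAULT_OPENING_THRESHOLD,
                   min_dwell: int = DEFAULT_MIN_DWELL) -> OpeningEvents:
    """Maximal runs above ``threshold`` lasting ≥ ``min_dwell`` frames.

    ``fraction_open`` is the fraction of all frames inside kept events.
    """
    if threshold <= 0:
        raise ParameterError("threshold must be positive")
    if min_dwell < 1:
        raise ParameterError("min_dwell must be ≥ 1")
    above = series.distances > threshold
    events: list[tuple[int, int]] = []
    start = None
    for k, flag in enumerate(above):
        if flag and start is None:
            start = k
        elif not flag and start is not None:
            if k - start >= min_dwell:
                events.append((start, k - 1))
            start = None
    if start is not None and len(above) - start >= min_dwell:
        events.append((start, len(above) - 1))
    n = len(series)
    inside = sum(e - s + 1 for s, e in events)
    return OpeningEvents(threshold=threshold, min_dwell=min_dwell, events=events,
                         fraction_open=inside / n if n else 0.0, n_frames=n)


def phe57_gate_distance(traj: Trajectory,
                        gate_resid: int = 57,
                        helix_segment: tuple[int, int] = (26, 34),
                        chain: str | None = None) -> DistanceSeries:
    """Distance from the portal-gate residue's side chain to the lid helix.

    Per frame: distance between the centroid of the gate residue's
    side-chain heavy atoms and the Cα centroid of the helix segment.  For
    Gly/Ala (or when side-chain atoms are absent) the gate falls back to its
    Cα, with a logged warning — this is exactly the degenerate case of an
    alanine-mutated gate.
    """
    topo = traj.topology
    chains = frozenset({chain}) if chain else None
    gate_all = [i for i, a in enumerate(topo)
                if a.resid == gate_resid and not a.is_hetero
                and (chain is None or a.chain == chain)]
    if not gate_all:
        raise SelectionError(f"gate residue {gate_resid} not present in topology")
    side = [i for i in gate_all
            if topo[i].name not in BACKBONE_NAMES and not topo[i].is_hydrogen]
    resname = topo[gate_all[0]].resname
    if resname in ("GLY", "ALA") or not side:
        if resname not in ("GLY", "ALA"):
            logger.warning("gate residue %s%d has no side-chain heavy atoms; "
                           "falling back to CA", resname, gate_resid)
        side = [i for i in gate_all if topo[i].name == "CA"]
        if not side:
            raise SelectionError(f"gate residue {gate_resid} has no CA either")
    helix_sel = Selection.calpha(chains=chains, resid_ranges=[helix_segment])
    ih = _group_indices(traj, helix_sel, "helix")
    gate_c = traj.frames[:, side, :].mean(axis=1)
    helix_c = traj.frames[:, ih, :].mean(axis=1)
    d = np.linalg.norm(gate_c - helix_c, axis=1)
    return DistanceSeries(
        frame_indices=np.arange(traj.n_frames), distances=d,
        descriptor={"mode": "gate-sidechain-to-helix", "gate_resid": gate_resid,
                    "gate_resname": resname, "helix_segment": list(helix_segment),
                    "gate_atoms": len(side), "helix_atoms": len(ih)},
    )
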
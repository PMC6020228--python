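"""Multi-model PDB reading/writing, atom selection and trajectory assembly.

The parser covers the fixed-column subset actually needed here
(ATOM/HETATM/MODEL/ENDMDL/TER).  Residue numbering is taken verbatim from
the file; no renumbering is performed, so analyses inherit whatever
convention the depositing structure uses (for P2-family structures this is
the conventional FABP numbering with the portal-gate Phe at 57, which
differs by −1 from some mutation reports).  Alternate locations other than
blank or "A" are dropped so every model has a single deterministic
conformer; insertion codes are rejected outright rather than silently
mangled.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import EmptyInputError, FormatError, TopologyError

# Standard amino acids; used for "standard residue" selections.
STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)
WATER_RESNAMES = frozenset({"HOH", "WAT", "H2O", "DOD", "TIP", "SOL"})
BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})


@dataclass(frozen=True)
class Atom:
    """A single atom record with protein-numbering identity and Å coordinates."""

    serial: int
    name: str
    element: str
    resname: str
    chain: str
    resid: int
    coords: tuple[float, float, float]
    is_hetero: bool = False

    @property
    def identity(self) -> tuple[str, int, str]:
        """(chain, resid, name) — the key that must be unique per model."""
        return (self.chain, self.resid, self.name)

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"


@dataclass
class Structure:
    """One model: an ordered list of atoms."""

    atoms: list[Atom]
    model_id: int = 1

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def identities(self) -> list[tuple[str, int, str]]:
        return [a.identity for a in self.atoms]


@dataclass
class Trajectory:
    """Fixed-topology coordinate series: F frames × N atoms × 3 (Å)."""

    topology: list[Atom]
    frames: np.ndarray
    frame_times: np.ndarray | None = None  # ns
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise TopologyError(f"frames must be F×N×3, got {self.frames.shape}")
        if self.frames.shape[1] != len(self.topology):
            raise TopologyError(
                f"{self.frames.shape[1]} coordinates per frame but "
                f"{len(self.topology)} topology atoms"
            )
        if self.frames.shape[0] < 1:
            raise TopologyError("a trajectory needs at least one frame")
        if self.frame_times is not None:
            t = np.asarray(self.frame_times, dtype=float)
            if len(t) != self.n_frames or np.any(np.diff(t) <= 0):
                raise TopologyError("frame_times must match F and increase strictly")
            self.frame_times = t

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


@dataclass(frozen=True)
class Selection:
    """Declarative atom filter resolving to a deterministic ordered index list.

    ``resid_ranges`` are inclusive on both ends.  ``None`` fields do not
    filter.  ``include_hetero=False`` (the default) drops HETATM records such
    as ligands and ions; water is only reachable with ``include_hetero=True``.
    """

    chains: frozenset[str] | None = None
    resid_ranges: tuple[tuple[int, int], ...] | None = None
    names: frozenset[str] | None = None
    heavy_only: bool = False
    include_hetero: bool = False

    @classmethod
    def calpha(cls, chains: Iterable[str] | None = None,
               resid_ranges: Iterable[tuple[int, int]] | None = None) -> "Selection":
        """Cα atoms of standard residues, the default fit/analysis set."""
        return cls(
            chains=frozenset(chains) if chains else None,
            resid_ranges=tuple(tuple(r) for r in resid_ranges) if resid_ranges else None,
            names=frozenset({"CA"}),
        )

    def matches(self, atom: Atom) -> bool:
        if not self.include_hetero and atom.is_hetero:
            return False
        if self.heavy_only and atom.is_hydrogen:
            return False
        if self.chains is not None and atom.chain not in self.chains:
            return False
        if self.names is not None and atom.name not in self.names:
            return False
        if self.resid_ranges is not None:
            if not any(lo <= atom.resid <= hi for lo, hi in self.resid_ranges):
                return False
        return True


def select(structure: Structure, selection: Selection) -> list[int]:
    """Ordered atom indices matching ``selection`` (empty list is valid)."""
    return [i for i, a in enumerate(structure.atoms) if selection.matches(a)]


def _guess_element(name: str) -> str:
    stripped = name.strip()
    if stripped and stripped[0].isdigit():  # e.g. 1HB2
        stripped = stripped.lstrip("0123456789")
    if not stripped:
        return "X"
    if len(stripped) >= 2 and stripped[:2].upper() in {"FE", "ZN", "MG", "MN", "CL", "BR", "NA", "CA"}:
        # two-letter elements only trusted when the name starts in column 13
        # (handled by caller via element field); fall through to first letter
        pass
    return stripped[0].upper()


def _parse_atom_line(line: str, lineno: int) -> Atom | None:
    """Parse one ATOM/HETATM record; None if the altloc filter drops it."""
    if len(line.rstrip("\n")) < 54:
        raise FormatError(f"line {lineno}: ATOM/HETATM record shorter than 54 columns")
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16]
        resname = line[17:20].strip()
        chain = line[21]
        resid = int(line[22:26])
        icode = line[26]
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise FormatError(f"line {lineno}: cannot parse ATOM/HETATM fields ({exc})") from None
    if icode not in (" ", ""):
        raise FormatError(f"line {lineno}: insertion codes are not supported (icode {icode!r})")
    if altloc not in (" ", "", "A"):
        return None
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = _guess_element(name)
    if not (np.isfinite(x) and np.isfinite(y) and np.isfinite(z)):
        raise FormatError(f"line {lineno}: non-finite coordinates")
    return Atom(
        serial=serial, name=name, element=element.capitalize() if len(element) > 1 else element.upper(),
        resname=resname, chain=chain, resid=resid,
        coords=(x, y, z), is_hetero=line.startswith("HETATM"),
    )


def read_pdb(source) -> list[Structure]:
    """Read a PDB text stream/string/path into one Structure per model.

    A file without MODEL records yields a single implicit model.  Raises
    :class:`FormatError` with the offending line number on malformed records
    and :class:`EmptyInputError` when no atoms are found.
    """
    if isinstance(source, str):
        if "\n" in source or source.lstrip().startswith(("ATOM", "HETATM", "MODEL", "REMARK", "HEADER")):
            stream = io.StringIO(source)
        else:
            stream = open(source)
    else:
        stream = source

    structures: list[Structure] = []
    current: list[Atom] = []
    in_model = False
    model_id = 0
    try:
        for lineno, line in enumerate(stream, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                if in_model:
                    raise FormatError(f"line {lineno}: MODEL inside an open MODEL block")
                in_model = True
                try:
                    model_id = int(line[6:].split()[0])
                except (ValueError, IndexError):
                    model_id += 1
                current = []
            elif rec == "ENDMDL":
                if not in_model:
                    raise FormatError(f"line {lineno}: ENDMDL without MODEL")
                structures.append(Structure(atoms=current, model_id=model_id))
                in_model = False
                current = []
            elif rec in ("ATOM  ", "HETATM"):
                atom = _parse_atom_line(line, lineno)
                if atom is not None:
                    current.append(atom)
            # TER / REMARK / everything else: ignored
    finally:
        if stream is not source:
            stream.close()

    if in_model:
        raise FormatError("unterminated MODEL block at end of input")
    if current:  # implicit single model
        structures.append(Structure(atoms=current, model_id=model_id or 1))
    total = sum(len(s) for s in structures)
    if total == 0:
        raise EmptyInputError("no ATOM/HETATM records found")
    for s in structures:
        seen = set()
        for a in s.atoms:
            if a.identity in seen:
                raise FormatError(
                    f"model {s.model_id}: duplicate atom identity {a.identity}"
                )
            seen.add(a.identity)
    return structures


def _format_atom_line(a: Atom, serial: int) -> str:
    record = "HETATM" if a.is_hetero else "ATOM  "
    # column-13 alignment: 1-3 character names shift right for one-letter elements
    name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
    x, y, z = a.coords
    element = a.element.rjust(2)[:2]
    return (
        f"{record}{serial:5d} {name:<4s} {a.resname:<3s} {a.chain}{a.resid:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          {element}"
    )


def write_pdb(structures: Sequence[Structure] | Structure) -> str:
    """Serialize structures to PDB text, with MODEL blocks when more than one.

    All models must share their (chain, resid, name) topology.
    """
    if isinstance(structures, Structure):
        structures = [structures]
    if not structures:
        raise EmptyInputError("nothing to write")
    ref_ids = structures[0].identities()
    for s in structures[1:]:
        if s.identities() != ref_ids:
            raise TopologyError(
                f"model {s.model_id} topology differs from model {structures[0].model_id}"
            )
    lines: list[str] = []
    multi = len(structures) > 1
    for k, s in enumerate(structures, start=1):
        if multi:
            lines.append(f"MODEL     {k:4d}")
        for i, a in enumerate(s.atoms, start=1):
            lines.append(_format_atom_line(a, i))
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


def models_to_trajectory(structures: Sequence[Structure],
                         selection: Selection | None = None) -> Trajectory:
    """Stack a model series into a Trajectory over the selected atoms.

    Models must agree on the selected topology; the first differing atom is
    named in the error.
    """
    if not structures:
        raise EmptyInputError("no structures given")
    if selection is None:
        selection = Selection(include_hetero=True)
    idx0 = select(structures[0], selection)
    topo = [structures[0].atoms[i] for i in idx0]
    topo_ids = [a.identity for a in topo]
    frames = np.empty((len(structures), len(topo), 3), dtype=float)
    for m, s in enumerate(structures):
        idx = select(s, selection)
        ids = [s.atoms[i].identity for i in idx]
        if ids != topo_ids:
            detail = "atom count differs"
            for a, b in zip(ids, topo_ids):
                if a != b:
                    detail = f"first differing atom {a} vs {b}"
                    break
            raise TopologyError(f"model {s.model_id} (position {m}): {detail}")
        frames[m] = np.array([s.atoms[i].coords for i in idx], dtype=float)
    return Trajectory(topology=topo, frames=frames)


def trajectory_to_structures(traj: Trajectory) -> list[Structure]:
    """Inverse of :func:`models_to_trajectory` (identities from topology)."""
    out = []
    for m in range(traj.n_frames):
        atoms = [
            Atom(serial=a.serial, name=a.name, element=a.element, resname=a.resname,
                 chain=a.chain, resid=a.resid, coords=tuple(traj.frames[m, i]),
                 is_hetero=a.is_hetero)
            for i, a in enumerate(traj.topology)
        ]
        out.append(Structure(atoms=atoms, model_id=m + 1))
    return out
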
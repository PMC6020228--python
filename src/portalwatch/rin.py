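"""Contact-based residue interaction networks (RINs) and centrality analysis.

A RIN has one node per residue and an edge between two residues whenever
their minimum heavy-atom distance falls inside a contact window, 2.5–5.0 Å
by default (both endpoints inclusive).  Hydrogens are ignored; water never
enters the network; a bound ligand (hetero residue) becomes a node only on
request, because a buried ligand touching many residues tends to dominate
the network.

Two centralities are computed per node:

- normalized shortest-path betweenness (fractional counting over equal-
  length paths, normalization (n−1)(n−2)/2, unweighted edges);
- removal impact: the relative drop in global efficiency
  (mean over node pairs of 1/shortest-path-length) when the node is deleted.

Nodes are called *central* when the population Z-score of a centrality is
at least 2 (configurable).  The differential comparison reports residues
that become central in any variant structure but not in the reference, and
vice versa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .errors import (ComparisonError, DegenerateDataError, ParameterError)
from .structure_io import STANDARD_RESIDUES, WATER_RESNAMES, Structure

DEFAULT_DMIN = 2.5  # Å
DEFAULT_DMAX = 5.0  # Å
DEFAULT_Z_THRESHOLD = 2.0

NodeId = tuple[str, int, str]  # (chain, resid, resname)


@dataclass
class ContactNetwork:
    graph: nx.Graph  # nodes: NodeId; edge attr "distance" (min heavy-atom, Å)
    dmin: float
    dmax: float
    ligand_included: bool

    @property
    def nodes(self) -> list[NodeId]:
        return list(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def ligand_nodes(self) -> list[NodeId]:
        return [n for n, data in self.graph.nodes(data=True) if data.get("is_ligand")]

    def to_sif(self) -> str:
        """One edge per line: chain:resid:resname chain:resid:resname distance."""
        def fmt(n: NodeId) -> str:
            return f"{n[0]}:{n[1]}:{n[2]}"
        lines = [f"{fmt(a)} {fmt(b)} {d:.3f}"
                 for a, b, d in sorted(
                     (tuple(sorted((u, v))) + (dd["distance"],)
                      for u, v, dd in self.graph.edges(data=True)))]
        return "\n".join(lines) + ("\n" if lines else "")


@dataclass
class CentralityReport:
    nodes: list[NodeId]
    betweenness: dict[NodeId, float]
    removal_impact: dict[NodeId, float]
    z_betweenness: dict[NodeId, float]
    z_removal_impact: dict[NodeId, float]
    z_threshold: float
    metric: str  # which Z defines the central set
    central: set[NodeId]
    ligand_dominant: bool = False  # a ligand node holds the top betweenness
    parameters: dict = field(default_factory=dict)


@dataclass
class DifferentialCentrality:
    reference_central: set
    variant_central: list[set]
    gained: set  # central in ≥1 variant, not in reference
    lost: set    # central in reference, in no variant
    key: str = "resid+resname"


def _residue_groups(structure: Structure, include_ligand: bool):
    """Heavy atoms grouped by residue; (protein groups, ligand groups)."""
    protein: dict[NodeId, list[int]] = {}
    ligand: dict[NodeId, list[int]] = {}
    for i, a in enumerate(structure.atoms):
        if a.is_hydrogen or a.resname in WATER_RESNAMES:
            continue
        key = (a.chain, a.resid, a.resname)
        if a.is_hetero and a.resname not in STANDARD_RESIDUES:
            if include_ligand:
                ligand.setdefault(key, []).append(i)
        else:
            protein.setdefault(key, []).append(i)
    return protein, ligand


def detect_contacts(structure: Structure,
                    dmin: float = DEFAULT_DMIN,
                    dmax: float = DEFAULT_DMAX,
                    include_ligand: bool = False,
                    exclude_sequence_neighbors: bool = False) -> ContactNetwork:
    """Build the residue interaction network of one structure.

    Edge between residues A ≠ B iff the minimum over heavy-atom pairs of
    their distance lies in [dmin, dmax].  A pair whose closest atoms clash
    below dmin therefore has *no* edge.  ``exclude_sequence_neighbors``
    additionally drops |Δresid| = 1 pairs on the same chain.
    """
    if dmin >= dmax:
        raise ParameterError(f"dmin ({dmin}) must be < dmax ({dmax})")
    protein, ligand = _residue_groups(structure, include_ligand)
    groups = {**protein, **ligand}
    if len(protein) < 2:
        raise DegenerateDataError("structure has fewer than 2 protein residues")

    coords = structure.coords()
    atom_index: list[tuple[NodeId, int]] = []
    pts = []
    for node, idxs in groups.items():
        for i in idxs:
            atom_index.append((node, i))
            pts.append(coords[i])
    pts = np.asarray(pts)
    tree = cKDTree(pts)
    pairs = tree.query_pairs(r=dmax, output_type="ndarray")

    # reduce atom pairs within dmax to the minimum distance per residue pair
    min_dist: dict[tuple[NodeId, NodeId], float] = {}
    for ai, bi in pairs:
        na, ia = atom_index[ai]
        nb, ib = atom_index[bi]
        if na == nb:
            continue
        key = (na, nb) if na <= nb else (nb, na)
        d = float(np.linalg.norm(pts[ai] - pts[bi]))
        if d < min_dist.get(key, np.inf):
            min_dist[key] = d

    g = nx.Graph()
    for node in groups:
        g.add_node(node, is_ligand=node in ligand)
    for (na, nb), d in min_dist.items():
        if not (dmin <= d <= dmax):
            continue
        if exclude_sequence_neighbors and na[0] == nb[0] and abs(na[1] - nb[1]) == 1:
            continue
        g.add_edge(na, nb, distance=round(d, 6))
    return ContactNetwork(graph=g, dmin=dmin, dmax=dmax, ligand_included=include_ligand)


def betweenness(network: ContactNetwork) -> dict[NodeId, float]:
    """Normalized shortest-path betweenness (unweighted edges)."""
    if network.n_nodes == 0:
        raise DegenerateDataError("empty network")
    return nx.betweenness_centrality(network.graph, normalized=True)


def _efficiency(g: nx.Graph) -> float:
    return nx.global_efficiency(g)


def removal_impact(network: ContactNetwork) -> dict[NodeId, float]:
    """Relative global-efficiency drop on deleting each node.

    impact_i = (E(G) − E(G∖i)) / E(G), E = mean over pairs of 1/d(u,v)
    with 1/∞ = 0.  Negative values mean the deletion *raises* efficiency.
    """
    g = network.graph
    if g.number_of_nodes() < 3:
        raise DegenerateDataError("removal impact needs at least 3 nodes")
    e0 = _efficiency(g)
    if e0 <= 0.0:
        raise DegenerateDataError("network has no edges; efficiency is zero")
    out: dict[NodeId, float] = {}
    for node in g.nodes:
        h = g.copy()
        h.remove_node(node)
        out[node] = (e0 - _efficiency(h)) / e0
    return out


@dataclass
class ZScoreResult:
    zscores: dict
    central: set
    z_threshold: float


def centrality_zscores(values: dict, z_threshold: float = DEFAULT_Z_THRESHOLD) -> ZScoreResult:
    """Population Z-scores of a centrality; central set = {Z ≥ threshold}.

    When every node has the same value (SD = 0) all Z are 0 and nothing is
    central.
    """
    if len(values) < 2:
        raise DegenerateDataError("Z-scores need at least 2 nodes")
    arr = np.array(list(values.values()), dtype=float)
    mu = arr.mean()
    sd = arr.std()  # population SD
    if sd == 0.0:
        z = {k: 0.0 for k in values}
    else:
        z = {k: float((v - mu) / sd) for k, v in values.items()}
    central = {k for k, zv in z.items() if zv >= z_threshold}
    return ZScoreResult(zscores=z, central=central, z_threshold=z_threshold)


def centrality_report(network: ContactNetwork,
                      z_threshold: float = DEFAULT_Z_THRESHOLD,
                      metric: str = "removal_impact") -> CentralityReport:
    """Full per-structure centrality analysis.

    ``metric`` selects which Z-score defines the central set
    ("removal_impact", the default, or "betweenness").
    """
    if metric not in ("removal_impact", "betweenness"):
        raise ParameterError(f"unknown centrality metric {metric!r}")
    bt = betweenness(network)
    ri = removal_impact(network)
    zb = centrality_zscores(bt, z_threshold)
    zr = centrality_zscores(ri, z_threshold)
    central = zr.central if metric == "removal_impact" else zb.central
    ligands = set(network.ligand_nodes())
    dominant = False
    if ligands and bt:
        top = max(bt, key=bt.get)
        dominant = top in ligands
    return CentralityReport(
        nodes=network.nodes, betweenness=bt, removal_impact=ri,
        z_betweenness=zb.zscores, z_removal_impact=zr.zscores,
        z_threshold=z_threshold, metric=metric, central=central,
        ligand_dominant=dominant,
        parameters={"dmin": network.dmin, "dmax": network.dmax,
                    "ligand_included": network.ligand_included},
    )


def _default_key(node: NodeId):
    """Chain-agnostic residue key: crystal forms differ in chain naming."""
    return (node[1], node[2])


def compare_centrality(reference: CentralityReport,
                       variants: list[CentralityReport],
                       key=_default_key) -> DifferentialCentrality:
    """Differential central-residue sets: reference vs a family of variants.

    Nodes are matched by ``key`` (default: (resid, resname), chain dropped —
    variant structures from different crystal forms rarely share chain ids).
    A node absent from a report counts as non-central there.  ``gained`` is
    the union over variants of central keys not central in the reference;
    ``lost`` are reference-central keys central in no variant.
    """
    ref_keys = {key(n) for n in reference.nodes}
    var_key_space = set()
    for v in variants:
        var_key_space |= {key(n) for n in v.nodes}
    if not (ref_keys & var_key_space):
        raise ComparisonError("reference and variant node spaces do not overlap")
    ref_central = {key(n) for n in reference.central}
    var_central = [{key(n) for n in v.central} for v in variants]
    union_var = set().union(*var_central) if var_central else set()
    return DifferentialCentrality(
        reference_central=ref_central,
        variant_central=var_central,
        gained=union_var - ref_central,
        lost={k for k in ref_central if k not in union_var},
    )
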
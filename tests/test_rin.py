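"""Residue interaction networks against exhaustive oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest

from portalwatch.errors import (ComparisonError, DegenerateDataError,
                                ParameterError)
from portalwatch.rin import (CentralityReport, ContactNetwork, betweenness,
                             centrality_report, centrality_zscores,
                             compare_centrality, detect_contacts,
                             removal_impact)
from portalwatch.structure_io import Atom, Structure
from portalwatch.synthetic_data import build_toy_barrel

from conftest import make_atoms


# ---------------------------------------------------------------------------
# oracles

def brute_force_contacts(structure, dmin, dmax, include_ligand=False):
    """O(N²) all-pairs reference for the residue contact edge set."""
    from portalwatch.structure_io import STANDARD_RESIDUES, WATER_RESNAMES
    groups = {}
    for a in structure.atoms:
        if a.is_hydrogen or a.resname in WATER_RESNAMES:
            continue
        if a.is_hetero and a.resname not in STANDARD_RESIDUES and not include_ligand:
            continue
        groups.setdefault((a.chain, a.resid, a.resname), []).append(np.array(a.coords))
    edges = set()
    for na, nb in itertools.combinations(sorted(groups), 2):
        dmin_pair = min(np.linalg.norm(p - q)
                        for p in groups[na] for q in groups[nb])
        if dmin <= dmin_pair <= dmax:
            edges.add((na, nb))
    return edges


def brute_force_betweenness(g: nx.Graph) -> dict:
    """Normalized betweenness by explicit enumeration of all shortest paths."""
    n = g.number_of_nodes()
    score = {v: 0.0 for v in g.nodes}
    for s, t in itertools.combinations(g.nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        for path in paths:
            for v in path[1:-1]:
                score[v] += 1.0 / len(paths)
    norm = (n - 1) * (n - 2) / 2.0
    return {v: val / norm for v, val in score.items()}


def floyd_warshall_efficiency(g: nx.Graph) -> float:
    """Global efficiency from an independent all-pairs distance computation."""
    nodes = list(g.nodes)
    n = len(nodes)
    if n < 2:
        return 0.0
    index = {v: i for i, v in enumerate(nodes)}
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for u, v in g.edges:
        dist[index[u], index[v]] = dist[index[v], index[u]] = 1.0
    for k in range(n):
        dist = np.minimum(dist, dist[:, k, None] + dist[None, k, :])
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    inv[np.isinf(dist)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return inv.sum() / (n * (n - 1))


def random_graphs(n_graphs=60, max_nodes=8, seed=99):
    rng = np.random.default_rng(seed)
    graphs = [nx.path_graph(3), nx.path_graph(8), nx.cycle_graph(6),
              nx.complete_graph(4), nx.star_graph(5),
              nx.disjoint_union(nx.path_graph(3), nx.complete_graph(4))]
    while len(graphs) < n_graphs:
        n = int(rng.integers(3, max_nodes + 1))
        p = float(rng.uniform(0.2, 0.9))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if g.number_of_edges() > 0:
            graphs.append(g)
    return graphs


def as_network(g: nx.Graph) -> ContactNetwork:
    h = nx.relabel_nodes(g, {v: ("A", int(v), "ALA") for v in g.nodes})
    for v in h.nodes:
        h.nodes[v]["is_ligand"] = False
    for u, v in h.edges:
        h.edges[u, v]["distance"] = 4.0
    return ContactNetwork(graph=h, dmin=2.5, dmax=5.0, ligand_included=False)


# ---------------------------------------------------------------------------
# contact detection

def _two_residue_structure(gap):
    """Two 2-atom residues whose closest heavy atoms are ``gap`` Å apart."""
    coords = [[0.0, 0.0, 0.0], [0.0, 0.0, 1.5],
              [gap, 0.0, 0.0], [gap, 0.0, -1.5]]
    atoms = make_atoms(coords, names=["CA", "CB", "CA", "CB"],
                       resids=[1, 1, 2, 2])
    return Structure(atoms=atoms, model_id=1)


class TestDetectContacts:
    @pytest.mark.parametrize("gap,expect_edge", [
        (3.0, True),   # inside the window
        (2.5, True),   # inclusive lower endpoint
        (5.0, True),   # inclusive upper endpoint
        (2.0, False),  # clash: closest pair below dmin
        (6.0, False),  # out of reach
    ])
    def test_contact_window(self, gap, expect_edge):
        net = detect_contacts(_two_residue_structure(gap))
        assert (net.graph.number_of_edges() == 1) is expect_edge

    def test_invalid_window_rejected(self, toy_barrel):
        with pytest.raises(ParameterError):
            detect_contacts(toy_barrel, dmin=5.0, dmax=2.5)

    @pytest.mark.parametrize("include_ligand", [False, True])
    @pytest.mark.parametrize("radius", [4.2, 4.8, 6.0])
    def test_equals_brute_force_on_toy_barrels(self, radius, include_ligand):
        s = build_toy_barrel(radius=radius, with_ligand=True)
        net = detect_contacts(s, include_ligand=include_ligand)
        got = {tuple(sorted(e)) for e in net.graph.edges}
        assert got == brute_force_contacts(s, 2.5, 5.0, include_ligand)

    def test_edge_distances_within_window(self, toy_barrel):
        net = detect_contacts(toy_barrel)
        for _, _, d in net.graph.edges(data="distance"):
            assert 2.5 <= d <= 5.0

    def test_atom_order_permutation_invariant(self, rng, toy_barrel_ligand):
        perm = rng.permutation(len(toy_barrel_ligand.atoms))
        shuffled = Structure(
            atoms=[toy_barrel_ligand.atoms[i] for i in perm], model_id=1)
        e1 = {tuple(sorted(e)) for e in
              detect_contacts(toy_barrel_ligand, include_ligand=True).graph.edges}
        e2 = {tuple(sorted(e)) for e in
              detect_contacts(shuffled, include_ligand=True).graph.edges}
        assert e1 == e2

    def test_sequence_neighbor_exclusion(self, toy_barrel):
        full = detect_contacts(toy_barrel)
        pruned = detect_contacts(toy_barrel, exclude_sequence_neighbors=True)
        dropped = {tuple(sorted(e)) for e in full.graph.edges} - \
                  {tuple(sorted(e)) for e in pruned.graph.edges}
        assert dropped
        assert all(abs(a[1] - b[1]) == 1 for a, b in dropped)

    def test_water_never_included(self):
        s = _two_residue_structure(3.0)
        wat = Atom(serial=99, name="O", element="O", resname="HOH", chain="A",
                   resid=50, coords=(1.5, 0.0, 0.0), is_hetero=True)
        s2 = Structure(atoms=s.atoms + [wat], model_id=1)
        net = detect_contacts(s2, include_ligand=True)
        assert all(n[2] != "HOH" for n in net.nodes)

    def test_ligand_node_only_on_request(self, toy_barrel_ligand):
        assert detect_contacts(toy_barrel_ligand).ligand_nodes() == []
        assert len(detect_contacts(toy_barrel_ligand,
                                   include_ligand=True).ligand_nodes()) == 1


# ---------------------------------------------------------------------------
# centralities

class TestBetweenness:
    def test_path_graph_midpoint(self):
        vals = betweenness(as_network(nx.path_graph(3)))
        assert vals[("A", 1, "ALA")] == pytest.approx(1.0)
        assert vals[("A", 0, "ALA")] == pytest.approx(0.0)

    def test_complete_graph_all_zero(self):
        vals = betweenness(as_network(nx.complete_graph(4)))
        assert all(v == pytest.approx(0.0) for v in vals.values())

    def test_matches_enumeration_oracle_on_small_graphs(self):
        for g in random_graphs():
            net = as_network(g)
            got = betweenness(net)
            want = brute_force_betweenness(net.graph)
            for node in net.nodes:
                assert got[node] == pytest.approx(want[node], abs=1e-12)


class TestRemovalImpact:
    def test_path_cut_vertex_dominates(self):
        vals = removal_impact(as_network(nx.path_graph(3)))
        assert vals[("A", 1, "ALA")] > vals[("A", 0, "ALA")]
        assert vals[("A", 1, "ALA")] == pytest.approx(1.0)  # removal disconnects

    def test_complete_graph_symmetric(self):
        vals = removal_impact(as_network(nx.complete_graph(5)))
        assert len({round(v, 12) for v in vals.values()}) == 1

    def test_matches_efficiency_recomputation_oracle(self):
        for g in random_graphs(n_graphs=40):
            net = as_network(g)
            got = removal_impact(net)
            e0 = floyd_warshall_efficiency(net.graph)
            for node in net.nodes:
                h = net.graph.copy()
                h.remove_node(node)
                want = (e0 - floyd_warshall_efficiency(h)) / e0
                assert got[node] == pytest.approx(want, abs=1e-12)

    def test_too_small_network_rejected(self):
        with pytest.raises(DegenerateDataError):
            removal_impact(as_network(nx.path_graph(2)))


class TestZScores:
    def test_all_equal_values_give_empty_central_set(self):
        res = centrality_zscores({i: 2.5 for i in range(6)})
        assert all(z == 0.0 for z in res.zscores.values())
        assert res.central == set()

    def test_single_outlier_is_central(self):
        res = centrality_zscores({0: 0.0, 1: 0.0, 2: 0.0, 3: 0.0, 4: 10.0})
        # population SD of {0,0,0,0,10} is 4, so the outlier has Z = 2
        assert res.zscores[4] == pytest.approx(2.0)
        assert res.central == {4}

    def test_affine_invariance(self, rng):
        vals = {i: float(v) for i, v in enumerate(rng.standard_normal(10))}
        res1 = centrality_zscores(vals)
        res2 = centrality_zscores({k: 3.0 * v + 7.0 for k, v in vals.items()})
        for k in vals:
            assert res2.zscores[k] == pytest.approx(res1.zscores[k], abs=1e-9)
        assert res2.central == res1.central

    def test_single_node_rejected(self):
        with pytest.raises(DegenerateDataError):
            centrality_zscores({0: 1.0})


class TestLigandDominance:
    def test_buried_ligand_dominates_network(self, toy_barrel_ligand):
        net = detect_contacts(toy_barrel_ligand, include_ligand=True)
        lig = net.ligand_nodes()[0]
        assert net.graph.degree[lig] == 60  # touches every residue
        report = centrality_report(net)
        assert report.ligand_dominant

    def test_no_ligand_no_domination(self, toy_barrel):
        report = centrality_report(detect_contacts(toy_barrel))
        assert not report.ligand_dominant


# ---------------------------------------------------------------------------
# differential centrality

def _report(central_resids, all_resids=range(1, 11)):
    nodes = [("A", r, "ALA") for r in all_resids]
    central = {("A", r, "ALA") for r in central_resids}
    zero = {n: 0.0 for n in nodes}
    return CentralityReport(nodes=nodes, betweenness=zero, removal_impact=zero,
                            z_betweenness=zero, z_removal_impact=zero,
                            z_threshold=2.0, metric="removal_impact",
                            central=central)


class TestCompareCentrality:
    def test_identical_reports_no_changes(self):
        diff = compare_centrality(_report({3, 4}), [_report({3, 4})] * 3)
        assert diff.gained == set() and diff.lost == set()

    def test_union_rule_single_variant_gain(self):
        variants = [_report(set())] * 5 + [_report({7})]
        diff = compare_centrality(_report(set()), variants)
        assert diff.gained == {(7, "ALA")}

    def test_lost_requires_absence_from_all_variants(self):
        diff = compare_centrality(_report({3}), [_report(set()), _report({3})])
        assert diff.lost == set()
        diff = compare_centrality(_report({3}), [_report(set()), _report(set())])
        assert diff.lost == {(3, "ALA")}

    def test_gained_disjoint_from_reference(self, rng):
        for _ in range(20):
            ref = set(rng.choice(10, size=3, replace=False) + 1)
            var = set(rng.choice(10, size=3, replace=False) + 1)
            diff = compare_centrality(_report(ref), [_report(var)])
            assert not (diff.gained & diff.reference_central)

    def test_chain_agnostic_matching(self):
        ref = _report({5})
        variant = CentralityReport(
            nodes=[("B", r, "ALA") for r in range(1, 11)],
            betweenness={}, removal_impact={}, z_betweenness={},
            z_removal_impact={}, z_threshold=2.0, metric="removal_impact",
            central={("B", 5, "ALA")})
        diff = compare_centrality(ref, [variant])
        assert diff.gained == set() and diff.lost == set()

    def test_disjoint_node_spaces_rejected(self):
        other = CentralityReport(
            nodes=[("A", r, "GLY") for r in range(100, 105)],
            betweenness={}, removal_impact={}, z_betweenness={},
            z_removal_impact={}, z_threshold=2.0, metric="removal_impact",
            central=set())
        with pytest.raises(ComparisonError):
            compare_centrality(_report({1}), [other])

    def test_engineered_hub_gain_detected(self, toy_barrel):
        """Adding a shortcut hub to a variant structure surfaces in `gained`."""
        net_ref = detect_contacts(toy_barrel, exclude_sequence_neighbors=False)
        ref = centrality_report(net_ref, metric="betweenness")
        g = net_ref.graph.copy()
        hub = ("A", 999, "HUB")
        g.add_node(hub, is_ligand=False)
        # connect the hub to every fifth residue: shortest paths reroute
        for r in range(1, 61, 5):
            g.add_edge(hub, next(n for n in g.nodes if n[1] == r), distance=4.0)
        variant = centrality_report(
            ContactNetwork(graph=g, dmin=2.5, dmax=5.0, ligand_included=False),
            metric="betweenness")
        diff = compare_centrality(ref, [variant])
        assert (999, "HUB") in diff.gained
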
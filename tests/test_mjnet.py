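import itertools

import networkx as nx
import numpy as np
import pytest
from scipy.sparse.csgraph import minimum_spanning_tree

from ystrkit.io import AlleleCall, build_table
from ystrkit.mjnet import (
    build_network,
    epsilon_msn,
    export_network,
    median_joining,
    prepare_network_input,
    quasi_median,
    read_network_tabular,
)
from tests.conftest import make_record


def _mst_cost(haplos):
    d = np.abs(haplos[:, None, :] - haplos[None, :, :]).sum(2).astype(float)
    return float(minimum_spanning_tree(d).sum())


def steiner_minimum(terminals, max_extra=2):
    """Brute-force Steiner minimum over the bounding lattice."""
    terminals = np.asarray(terminals)
    lo, hi = terminals.min(0), terminals.max(0)
    grid = [
        np.array(p)
        for p in itertools.product(*(range(a, b + 1) for a, b in zip(lo, hi)))
    ]
    term_set = {tuple(t) for t in terminals}
    cands = [p for p in grid if tuple(p) not in term_set]
    best = _mst_cost(terminals)
    for k in range(1, max_extra + 1):
        for combo in itertools.combinations(cands, k):
            cost = _mst_cost(np.vstack([terminals, np.array(combo)]))
            best = min(best, cost)
    return best


class TestPrepare:
    def test_microvariant_rounds_half_up_and_dys385_excluded(self):
        recs = [make_record("A", overrides={"DYS458": AlleleCall.value(17.2)})]
        recs.append(make_record("B"))
        t = build_table(recs)
        haps, mult, annot, names = prepare_network_input(t)
        assert "DYS385" not in names and len(names) == 21
        j = names.index("DYS458")
        assert haps[:, j].tolist().count(17) >= 1  # 17.2 -> 17

    def test_identical_samples_collapse_with_multiplicity(self):
        t = build_table([make_record("A"), make_record("B")])
        haps, mult, annot, _ = prepare_network_input(t)
        assert len(haps) == 1 and mult[0] == 2
        assert annot[0]["clans"] == {"Kerderi": 2}

    def test_null_policies(self):
        recs = [make_record("A"),
                make_record("B", overrides={"DYS448": AlleleCall.null()})]
        t = build_table(recs)
        haps, _, _, names = prepare_network_input(t)
        assert len(haps) == 1  # sample with null dropped
        haps2, _, _, names2 = prepare_network_input(t, null_policy="drop-locus")
        assert len(haps2) == 1 and "DYS448" not in names2 and len(names2) == 20


class TestEpsilonMsn:
    def test_triangle_distances_1_1_2(self):
        h = np.array([[10, 10], [11, 10], [10, 11]])  # d = 1,1,2
        e0 = epsilon_msn(h, 0)
        assert e0 == {(0, 1), (0, 2)}
        e1 = epsilon_msn(h, 1)
        assert e1 == {(0, 1), (0, 2), (1, 2)}

    def test_chain_is_path_graph(self):
        h = np.array([[10, 10], [11, 10], [12, 10]])
        assert epsilon_msn(h, 0) == {(0, 1), (1, 2)}

    def test_msn_contains_every_brute_force_mst(self):
        rng = np.random.default_rng(17)
        h = np.unique(rng.integers(10, 14, size=(9, 3)), axis=0)
        d = np.abs(h[:, None, :] - h[None, :, :]).sum(2)
        n = len(h)
        msn = epsilon_msn(h, 0)
        all_edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
        best = None
        msts = []
        for combo in itertools.combinations(all_edges, n - 1):
            g = nx.Graph(combo)
            if g.number_of_nodes() == n and nx.is_connected(g):
                w = sum(d[i, j] for i, j in combo)
                if best is None or w < best - 1e-9:
                    best, msts = w, [set(combo)]
                elif abs(w - best) < 1e-9:
                    msts.append(set(combo))
        for tree in msts:
            assert tree <= msn  # every MST edge appears in the MSN


class TestQuasiMedian:
    def test_middle_value(self):
        assert quasi_median([14], [15], [16]) == (15,)

    def test_majority(self):
        a = [14, 10]
        assert quasi_median(a, a, [16, 12]) == tuple(a)

    def test_median_equal_to_input_not_added(self):
        # collinear triple: the median vector is the middle haplotype
        h = np.array([[10, 10], [11, 10], [12, 10]])
        net = median_joining(h, [1, 1, 1])
        assert len(net.median_nodes) == 0


class TestMedianJoining:
    def test_two_haplotypes_single_edge(self):
        h = np.array([[10, 10], [12, 11]])
        net = median_joining(h, [1, 1])
        assert net.graph.number_of_edges() == 1
        assert net.total_length() == 3

    def test_star_center_reconstructed(self):
        center = np.array([10, 10, 10, 10])
        terms = np.vstack([center + np.eye(4, dtype=int)[i] for i in range(4)])
        net = median_joining(terms, [1, 1, 1, 1])
        assert tuple(center) in net.median_nodes
        assert net.total_length() == 4.0
        assert net.total_length() == steiner_minimum(terms)

    def test_tree_without_homoplasy_recovered_exactly(self):
        # every node of a known genealogy sampled; one new locus per branch
        r = (10, 10, 10, 10, 10)
        a = (11, 10, 10, 10, 10)
        b = (11, 11, 10, 10, 10)
        c = (10, 10, 11, 10, 10)
        d = (10, 10, 11, 11, 10)
        true_edges = {(r, a), (a, b), (r, c), (c, d)}
        net = median_joining(np.array([r, a, b, c, d]), [1] * 5)
        got = {tuple(sorted(e)) for e in net.graph.edges()}
        want = {tuple(sorted(e)) for e in true_edges}
        assert got == want
        assert len(net.median_nodes) == 0

    def test_network_spans_samples_within_mst_cost(self):
        """At epsilon=0 the network connects every sampled haplotype and a
        spanning tree of it costs no more than the samples' own MST
        (medians may shorten, never lengthen, the backbone)."""
        rng = np.random.default_rng(5)
        h = np.unique(rng.integers(10, 13, size=(10, 4)), axis=0)
        net = median_joining(h, [1] * len(h))
        for hap in h:
            assert tuple(hap) in net.graph
        assert nx.is_connected(net.graph)
        net_mst = nx.minimum_spanning_tree(net.graph, weight="steps")
        net_cost = sum(w for _, _, w in net_mst.edges(data="steps"))
        assert net_cost <= _mst_cost(h) + 1e-9

    def test_length_bounded_below_by_steiner_minimum(self):
        rng = np.random.default_rng(23)
        terms = np.unique(rng.integers(10, 12, size=(6, 4)), axis=0)
        net = median_joining(terms, [1] * len(terms))
        assert net.total_length() >= steiner_minimum(terms, max_extra=3) - 1e-9

    def test_sampled_nodes_all_present_and_connected(self, small_tribe):
        table, _ = small_tribe
        net = build_network(table)
        haps, mult, _, _ = prepare_network_input(table)
        for h in haps:
            assert tuple(h) in net.graph
        assert nx.is_connected(net.graph)
        assert all(w >= 1 for _, _, w in net.graph.edges(data="steps"))


class TestExport:
    def test_graphml_round_trips_through_networkx(self, tmp_path):
        h = np.array([[10, 10], [12, 10]])
        net = median_joining(h, [2, 1])
        path = tmp_path / "net.graphml"
        export_network(net, path, "graphml")
        g = nx.read_graphml(path)
        assert g.number_of_nodes() == 2 and g.number_of_edges() == 1
        mults = {d["multiplicity"] for _, d in g.nodes(data=True)}
        assert mults == {1, 2}

    def test_dot_output_is_plain_graphviz(self, tmp_path):
        h = np.array([[10, 10], [12, 10]])
        net = median_joining(h, [1, 1])
        path = tmp_path / "net.dot"
        export_network(net, path, "dot")
        text = path.read_text()
        assert text.startswith("graph") and "--" in text

    def test_tabular_round_trip(self, tmp_path):
        h = np.array([[10, 10, 10], [12, 10, 10], [10, 11, 10]])
        net = median_joining(h, [2, 1, 3])
        path = tmp_path / "net.tsv"
        export_network(net, path, "tabular")
        back = read_network_tabular(path)
        assert set(back.graph.nodes) == set(net.graph.nodes)
        assert {tuple(sorted(e)) for e in back.graph.edges} == {
            tuple(sorted(e)) for e in net.graph.edges
        }

    def test_unknown_format_rejected(self, tmp_path):
        h = np.array([[10, 10], [12, 10]])
        net = median_joining(h, [1, 1])
        with pytest.raises(ValueError):
            export_network(net, tmp_path / "x", "svg")
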
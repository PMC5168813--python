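"""Correlation thresholding, graph measures, Walktrap and structural balance."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from seedmet import (adjust_p_matrix, assemble_metabolite_sets, bh_fdr,
                     build_network, frustration, germination_edge_report,
                     network_attributes, signed_bipartition, spearman_matrix,
                     threshold_scan, walktrap_communities)


class TestSpearman:
    def test_monotone_pairs(self):
        df = pd.DataFrame({"a": [1, 2, 3, 4, 5], "b": [2, 4, 9, 16, 100],
                           "c": [5, 4, 3, 2, 1]})
        r, p = spearman_matrix(df, min_n=3)
        assert r.loc["a", "b"] == pytest.approx(1.0)
        assert r.loc["a", "c"] == pytest.approx(-1.0)
        assert p.loc["a", "b"] == 0.0

    def test_rank_formula_example(self):
        df = pd.DataFrame({"x": [1, 2, 3, 4], "y": [2, 1, 4, 3]})
        r, _ = spearman_matrix(df, min_n=3)
        assert r.loc["x", "y"] == pytest.approx(0.6)

    def test_matches_reference_on_complete_data(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(30, 5)),
                          columns=list("abcde"))
        r, p = spearman_matrix(df)
        ref_r, ref_p = stats.spearmanr(df.to_numpy())
        np.testing.assert_allclose(r.to_numpy(), ref_r, atol=1e-12)
        iu = np.triu_indices(5, 1)
        np.testing.assert_allclose(p.to_numpy()[iu], ref_p[iu], atol=1e-10)

    def test_constant_column_excluded(self):
        df = pd.DataFrame({"a": [1, 2, 3, 4], "b": [2, 1, 4, 3],
                           "const": [7.0] * 4})
        r, _ = spearman_matrix(df, min_n=3)
        assert "const" not in r.columns

    def test_pairwise_deletion_uses_complete_pairs(self):
        df = pd.DataFrame({"a": [1, 2, 3, 4, 5, 6],
                           "b": [1, 2, 3, 4, 5, np.nan],
                           "c": [6, 5, 4, 3, 2, 1]})
        r, _ = spearman_matrix(df)
        assert r.loc["a", "b"] == pytest.approx(1.0)
        assert r.loc["b", "c"] == pytest.approx(-1.0)


class TestFDR:
    def test_step_up_hand_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_and_equal_values(self):
        np.testing.assert_allclose(bh_fdr([0.3]), [0.3])
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_matches_reference_implementation(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(1)
        p = rng.random(500)
        np.testing.assert_allclose(bh_fdr(p),
                                   multipletests(p, method="fdr_bh")[1],
                                   atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


def _matrices(r_dict, nodes):
    r = pd.DataFrame(np.eye(len(nodes)), index=nodes, columns=nodes)
    p = pd.DataFrame(np.zeros((len(nodes), len(nodes))), index=nodes,
                     columns=nodes)
    for (u, v), val in r_dict.items():
        r.loc[u, v] = r.loc[v, u] = val
    return r, p


class TestBuildNetwork:
    def test_threshold_one_keeps_only_perfect_pairs(self):
        r, p = _matrices({("a", "b"): 1.0, ("a", "c"): 0.8,
                          ("b", "c"): -1.0}, list("abc"))
        net = build_network(r, p, r_min=1.0, q=0.05)
        assert set(map(frozenset, net.edges())) == {frozenset("ab"),
                                                    frozenset("bc")}

    def test_zero_q_empty_network(self):
        r, p = _matrices({("a", "b"): 0.9}, list("ab"))
        net = build_network(r, p, r_min=0.4, q=0.0)
        assert net.number_of_nodes() == 0

    def test_sign_attribute(self):
        r, p = _matrices({("a", "b"): 0.9, ("b", "c"): -0.7}, list("abc"))
        net = build_network(r, p)
        assert net["a"]["b"]["sign"] == 1
        assert net["b"]["c"]["sign"] == -1

    def test_retention_monotone_in_q_and_r_min(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(40, 8)))
        df.iloc[:, 1] = df.iloc[:, 0] + rng.normal(0, 0.5, 40)
        df.columns = [f"m{i}" for i in range(8)]
        r, p = spearman_matrix(df)
        p_adj = adjust_p_matrix(p)
        prev = np.inf
        for r_min in (0.0, 0.2, 0.4, 0.6, 0.8):
            e = build_network(r, p_adj, r_min=r_min).number_of_edges()
            assert e <= prev
            prev = e
        prev = 0
        for q in (0.001, 0.05, 0.5, 1.0):
            e = build_network(r, p_adj, r_min=0.0, q=q).number_of_edges()
            assert e >= prev
            prev = e


class TestAttributes:
    def test_triangle(self):
        net = nx.Graph()
        net.add_edges_from([("a", "b"), ("b", "c"), ("a", "c")], sign=1, r=0.9)
        a = network_attributes(net)
        assert (a.density, a.transitivity, a.diameter, a.avg_path_length) \
            == (1.0, 1.0, 1.0, 1.0)
        assert a.n_edges == a.n_pos_edges == 3

    def test_four_node_path(self):
        net = nx.path_graph(4)
        nx.set_edge_attributes(net, 1, "sign")
        a = network_attributes(net)
        assert a.diameter == 3
        assert a.density == pytest.approx(0.5)
        assert a.transitivity == 0.0
        assert a.avg_path_length == pytest.approx(10 / 6)

    def test_star(self):
        net = nx.star_graph(4)
        nx.set_edge_attributes(net, 1, "sign")
        a = network_attributes(net)
        assert a.avg_degree == pytest.approx(1.6)
        assert a.transitivity == 0.0

    def test_identities_hold(self):
        rng = np.random.default_rng(3)
        net = nx.gnp_random_graph(12, 0.4, seed=5)
        nx.set_edge_attributes(net, 1, "sign")
        a = network_attributes(net)
        n, e = a.n_nodes, a.n_edges
        assert a.density == pytest.approx(2 * e / (n * (n - 1)))
        assert a.avg_degree == pytest.approx(2 * e / n)
        assert a.n_edges == a.n_pos_edges + a.n_neg_edges

    def test_threshold_scan_consistent_and_monotone(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(50, 6)),
                          columns=[f"m{i}" for i in range(6)])
        df["m1"] = df["m0"] * 0.9 + rng.normal(0, 0.3, 50)
        r, p = spearman_matrix(df)
        p_adj = adjust_p_matrix(p)
        scan = threshold_scan(r, p_adj, [0.0, 0.2, 0.4, 0.6])
        assert (scan["n_edges"].diff().dropna() <= 0).all()
        direct = build_network(r, p_adj, r_min=0.4)
        row = scan[scan["r_min"] == 0.4].iloc[0]
        assert row["n_edges"] == direct.number_of_edges()


class TestWalktrap:
    def test_two_cliques_with_bridge(self):
        net = nx.Graph()
        for offset, names in ((0, "abcd"), (1, "wxyz")):
            for u, v in itertools.combinations(names, 2):
                net.add_edge(u, v, sign=1, r=0.9, weight=0.9)
        net.add_edge("a", "w", sign=1, r=0.9, weight=0.9)
        part = walktrap_communities(net)
        groups = {}
        for node, cid in part.items():
            groups.setdefault(cid, set()).add(node)
        assert set(map(frozenset, groups.values())) == {frozenset("abcd"),
                                                        frozenset("wxyz")}

    def test_uniform_complete_graph_single_community(self):
        net = nx.complete_graph(6)
        nx.set_edge_attributes(net, 1.0, "weight")
        nx.set_edge_attributes(net, 1, "sign")
        part = walktrap_communities(net)
        assert len(set(part.values())) == 1

    def test_disjoint_cliques_recovered(self):
        net = nx.Graph()
        for names in ("abcd", "efgh", "ijkl"):
            for u, v in itertools.combinations(names, 2):
                net.add_edge(u, v, sign=1, r=1.0, weight=1.0)
        part = walktrap_communities(net)
        assert len(set(part.values())) == 3


def _exhaustive_min_frustration(net, weighted=True):
    nodes = sorted(net.nodes())
    best = np.inf
    for bits in itertools.product((0, 1), repeat=len(nodes) - 1):
        side = {nodes[0]: 0, **dict(zip(nodes[1:], bits))}
        best = min(best, frustration(net, side, weighted))
    return best


class TestSignedBipartition:
    def test_all_positive_single_subset(self):
        net = nx.complete_graph(5)
        nx.set_edge_attributes(net, 1, "sign")
        nx.set_edge_attributes(net, 0.8, "r")
        a, b, f = signed_bipartition(net)
        assert len(a) == 5 and len(b) == 0 and f == 0.0

    def test_balanced_four_cycle(self):
        net = nx.Graph()
        net.add_edge("a", "b", sign=1, r=0.9)
        net.add_edge("b", "c", sign=-1, r=0.9)
        net.add_edge("c", "d", sign=1, r=0.9)
        net.add_edge("d", "a", sign=-1, r=0.9)
        a, b, f = signed_bipartition(net)
        assert f == 0.0
        assert {frozenset(a), frozenset(b)} == {frozenset("ab"), frozenset("cd")}

    def test_unbalanced_triangle(self):
        net = nx.Graph()
        net.add_edge("a", "b", sign=1, r=1.0)
        net.add_edge("b", "c", sign=1, r=1.0)
        net.add_edge("a", "c", sign=-1, r=1.0)
        _, _, f = signed_bipartition(net, weighted=False)
        assert f == 1.0

    @pytest.mark.parametrize("seed", range(20))
    def test_heuristic_matches_exact_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        net = nx.gnp_random_graph(n, 0.5, seed=seed)
        for u, v in net.edges():
            net[u][v]["sign"] = int(rng.choice([-1, 1]))
            net[u][v]["r"] = float(rng.uniform(0.4, 1.0))
        if net.number_of_edges() == 0:
            pytest.skip("empty random graph")
        _, _, f_exact = signed_bipartition(net, method="exact")
        _, _, f_heur = signed_bipartition(net, method="heuristic")
        assert f_heur == pytest.approx(f_exact, abs=1e-9)
        assert f_exact == pytest.approx(_exhaustive_min_frustration(net),
                                        abs=1e-9)


def _two_set_network():
    """Two communities, each split into antagonistic subsets, plus traits."""
    net = nx.Graph()
    ms1 = ["m1", "m2", "m3"]
    ms2 = ["m4", "m5", "m6"]
    for group in (ms1, ms2):
        for u, v in itertools.combinations(group, 2):
            net.add_edge(u, v, sign=1, r=0.8, weight=0.8, p_adj=1e-4)
    for u in ms1:
        for v in ms2:
            net.add_edge(u, v, sign=-1, r=-0.7, weight=0.7, p_adj=1e-4)
    for u in ms1:
        net.add_edge("percent", u, sign=-1, r=-0.6, weight=0.6, p_adj=1e-4)
    for v in ms2:
        net.add_edge("percent", v, sign=1, r=0.6, weight=0.6, p_adj=1e-4)
    net.add_edge("t50", "m1", sign=1, r=0.5, weight=0.5, p_adj=1e-4)
    return net, ms1, ms2


class TestAssembleSets:
    def _run(self, net):
        met_nodes = [v for v in net.nodes() if v not in ("percent", "t50",
                                                         "sd_plate")]
        met_net = net.subgraph(met_nodes)
        partition = walktrap_communities(met_net)
        bip = {}
        for cid in sorted(set(partition.values())):
            members = [v for v, c in partition.items() if c == cid]
            bip[cid] = signed_bipartition(met_net.subgraph(members))
        return assemble_metabolite_sets(partition, bip, net,
                                        germination_percent_node="percent")

    def test_clean_bipartition_oriented_by_germination(self):
        net, ms1, ms2 = _two_set_network()
        sets = self._run(net)
        assert sets.members("ms1") == set(ms1)
        assert sets.members("ms2") == set(ms2)
        assert sets.frustrated_edges == 0
        assert sets.orientation_defined

    def test_germination_sign_flip_swaps_set_labels(self):
        # flipping the germination-trait correlations reverses which side of
        # the (unchanged) metabolite bipartition gets the ms1 label
        net, ms1, ms2 = _two_set_network()
        flipped = net.copy()
        for u, v, d in flipped.edges(data=True):
            if "percent" in (u, v) or "t50" in (u, v):
                d["sign"] *= -1
                d["r"] *= -1
        sets = self._run(flipped)
        assert sets.members("ms1") == set(ms2)
        assert sets.members("ms2") == set(ms1)

    def test_germination_edge_report_matches_construction(self):
        net, ms1, ms2 = _two_set_network()
        sets = self._run(net)
        report = germination_edge_report(net, sets)
        assert report["consistent"].all()
        percent_rows = report[report["trait"] == "percent"]
        assert len(percent_rows) == 6
        neg = percent_rows[percent_rows["sign"] < 0]
        assert set(neg["metabolite"]) == set(ms1)
        t50_rows = report[report["trait"] == "t50"]
        assert list(t50_rows["metabolite"]) == ["m1"]
        assert t50_rows["expected_set"].iloc[0] == "ms1"
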
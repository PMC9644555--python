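"""Edge filtering/classification, centralities, and the leave-one-out test."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from xtaxnet import (
    annotate_da,
    centrality_metrics,
    classify_edges,
    influential_taxa,
    intra_modular_edges,
)
from xtaxnet.influence import EdgeList, InfluenceReport, wilcoxon_signed_rank

from conftest import corr_estimate


def wilcoxon_enumeration(d: np.ndarray) -> float:
    """Full 2^n sign enumeration, two-sided, matching the exact convention."""
    d = np.asarray(d, float)
    d = d[d != 0]
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.array(
        [ranks[np.array(signs, bool)].sum() for signs in itertools.product([0, 1], repeat=n)]
    )
    return min(1.0, 2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean()))


def edge_list(pairs, condition="A", r=0.5, q=0.01) -> EdgeList:
    rows = [
        {"taxon_a": min(a, b), "taxon_b": max(a, b), "r": r, "q": q, "same_module": True}
        for a, b in pairs
    ]
    return EdgeList(
        edges=pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "r", "q", "same_module"]),
        condition=condition,
    )


class TestIntraModularEdges:
    @pytest.mark.parametrize(
        "r,q,kept",
        [(0.20, 0.05, True), (0.19, 0.001, False), (0.9, 0.2, False), (0.5, 0.01, True)],
    )
    def test_filter_boundaries_inclusive(self, r, q, kept):
        corr = corr_estimate(["a", "b", "c"], {("a", "b"): (r, q)})
        edges = intra_modular_edges(corr, labels=[1, 1, 1])
        assert (len(edges.edges) == 1) is kept

    def test_same_module_flag_and_label_zero(self):
        corr = corr_estimate(
            ["a", "b", "c", "d"],
            {("a", "b"): (0.6, 0.01), ("c", "d"): (0.6, 0.01)},
        )
        edges = intra_modular_edges(corr, labels=[1, 1, 0, 0])
        flags = dict(zip(zip(edges.edges["taxon_a"], edges.edges["taxon_b"]), edges.edges["same_module"]))
        assert flags[("a", "b")] is True or flags[("a", "b")] == True  # noqa: E712
        assert not flags[("c", "d")]


class TestClassifyEdges:
    def test_identical_sets_all_shared(self):
        e = edge_list([("a", "b"), ("b", "c")])
        cls = classify_edges(e, e)
        assert cls.counts() == {"shared": 2}

    def test_disjoint_sets_no_shared(self):
        cls = classify_edges(edge_list([("a", "b")]), edge_list([("c", "d")]))
        counts = cls.counts()
        assert counts.get("shared", 0) == 0
        assert counts["disease_only"] == 1 and counts["control_only"] == 1

    def test_partition_and_swap_symmetry(self):
        rng = np.random.default_rng(41)
        nodes = [f"t{i}" for i in range(10)]
        all_pairs = list(itertools.combinations(nodes, 2))
        pa = [all_pairs[i] for i in rng.choice(len(all_pairs), 15, replace=False)]
        pb = [all_pairs[i] for i in rng.choice(len(all_pairs), 12, replace=False)]
        ab = classify_edges(edge_list(pa), edge_list(pb)).counts()
        ba = classify_edges(edge_list(pb), edge_list(pa)).counts()
        union = len(set(pa) | set(pb))
        assert sum(ab.values()) == union
        assert ab.get("disease_only", 0) == ba.get("control_only", 0)
        assert ab.get("shared", 0) == ba.get("shared", 0)


class TestCentralityMetrics:
    def test_star_graph_closed_form(self):
        g = nx.star_graph(4)  # center 0, leaves 1..4
        m = centrality_metrics(g)
        assert m.loc[0, "degree_n"] == 1.0
        assert m.loc[1, "degree_n"] == 0.25

    def test_triangle_closed_form(self):
        g = nx.complete_graph(3)
        m = centrality_metrics(g)
        assert np.allclose(m["transitivity_local"], 1.0)
        assert np.allclose(m["closeness_n"], 1.0)

    def test_path_three_nodes(self):
        g = nx.path_graph(3)
        m = centrality_metrics(g)
        assert m.loc[1, "closeness_n"] == pytest.approx(1.0)
        assert m.loc[0, "closeness_n"] == pytest.approx(2 / 3)

    def test_singleton_component_closeness_zero(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        g.add_node("c")
        m = centrality_metrics(g)
        assert m.loc["c", "closeness_n"] == 0.0
        assert m.loc["c", "transitivity_local"] == 0.0

    def test_matches_igraph_on_random_connected_graphs(self):
        import igraph

        rng = np.random.default_rng(42)
        checked = 0
        while checked < 50:
            n = int(rng.integers(5, 30))
            g = nx.gnp_random_graph(n, 0.25, seed=int(rng.integers(2**31)))
            if not nx.is_connected(g):
                continue
            checked += 1
            m = centrality_metrics(g)
            ig = igraph.Graph(n=n, edges=list(g.edges))
            deg_ref = np.array(ig.degree()) / (n - 1)
            clo_ref = np.array(ig.closeness(normalized=True))
            tra_ref = np.array(ig.transitivity_local_undirected(mode="zero"))
            assert np.max(np.abs(m["degree_n"].to_numpy() - deg_ref)) < 1e-12
            assert np.max(np.abs(m["closeness_n"].to_numpy() - clo_ref)) < 1e-12
            assert np.max(np.abs(m["transitivity_local"].to_numpy() - tra_ref)) < 1e-12

    def test_removing_isolated_node_changes_nothing(self):
        rng = np.random.default_rng(43)
        for seed in range(10):
            g = nx.gnp_random_graph(12, 0.3, seed=seed)
            g.add_node("isolated")
            before = centrality_metrics(g).drop(index="isolated")
            g2 = g.copy()
            g2.remove_node("isolated")
            after = centrality_metrics(g2)
            # removing a degree-0 node rescales nothing but n; metrics that
            # depend on n (degree_n, closeness_n WF factor) change by the
            # n-scaling only, so compare on raw structure via equal ranks
            assert np.allclose(
                before["transitivity_local"], after["transitivity_local"]
            )


class TestWilcoxon:
    def test_exact_matches_enumeration(self):
        rng = np.random.default_rng(44)
        for _ in range(100):
            n = int(rng.integers(5, 11))
            d = rng.normal(size=n)
            assert wilcoxon_signed_rank(d) == pytest.approx(
                wilcoxon_enumeration(d), abs=1e-12
            )

    def test_hand_set_vector_n6(self):
        d = np.array([1.2, -0.4, 2.2, 0.9, 1.5, 0.3])
        assert wilcoxon_signed_rank(d) == pytest.approx(wilcoxon_enumeration(d), abs=1e-12)

    def test_all_zero_differences(self):
        assert wilcoxon_signed_rank(np.zeros(8)) == 1.0


class TestInfluentialTaxa:
    def _run(self, edges, taxa, labels):
        return influential_taxa(
            edges, taxa, labels, edge_list([], "B"), taxa, np.zeros(len(taxa), int)
        )

    def test_hub_removal_flagged(self):
        # hub connected to all 20 nodes of a sparse ring: removal drops
        # every node's degree
        nodes = [f"n{i:02d}" for i in range(20)]
        ring = [(nodes[i], nodes[(i + 1) % 20]) for i in range(20)]
        spokes = [("hub", v) for v in nodes]
        edges = edge_list(ring + spokes)
        taxa = nodes + ["hub"]
        labels = np.ones(len(taxa), int)
        report = self._run(edges, taxa, labels)
        row = report.table.set_index("taxon").loc["hub"]
        assert row["influential"]
        assert row["q_degree_n"] <= 0.05

    def test_isolated_taxon_not_influential(self):
        nodes = ["a", "b", "c", "d", "e", "f", "iso"]
        edges = edge_list(list(itertools.combinations(nodes[:6], 2)))
        labels = np.ones(len(nodes), int)
        report = self._run(edges, nodes, labels)
        row = report.table.set_index("taxon").loc["iso"]
        assert not row["influential"]
        assert row["underpowered"]

    def test_label_zero_taxa_not_candidates(self):
        nodes = ["a", "b", "c"]
        edges = edge_list([("a", "b")])
        report = self._run(edges, nodes, np.array([1, 1, 0]))
        assert "c" not in set(report.table["taxon"])


class TestAnnotateDA:
    def _report(self):
        return InfluenceReport(
            table=pd.DataFrame(
                {"taxon": ["g__A", "g__B"], "influential": [True, False]}
            )
        )

    def test_per_method_flags_joined(self):
        da = pd.DataFrame(
            {
                "taxon": ["g__A", "g__A", "g__B"],
                "level": ["Genus"] * 3,
                "method": ["ALDEx2", "ANCOMBC", "ALDEx2"],
                "significant": [True, False, False],
            }
        )
        out = annotate_da(self._report(), da)
        assert out.set_index("taxon").loc["g__A", "ALDEx2_significant"] == True  # noqa: E712
        assert out.set_index("taxon").loc["g__A", "ANCOMBC_significant"] == False  # noqa: E712

    def test_empty_table_adds_na_columns(self):
        da = pd.DataFrame(columns=["taxon", "level", "method", "significant"])
        out = annotate_da(self._report(), da)
        assert len(out) == 2

    def test_duplicate_rows_error(self):
        da = pd.DataFrame(
            {
                "taxon": ["g__A", "g__A"],
                "level": ["Genus"] * 2,
                "method": ["ALDEx2", "ALDEx2"],
                "significant": [True, False],
            }
        )
        with pytest.raises(ValueError, match="duplicate"):
            annotate_da(self._report(), da)
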
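"""Intra-modular networks, edge classification, and influential taxa.

Edges are taxa-taxa correlations passing r >= 0.2 and BH q <= 0.05 (both
bounds inclusive); the intra-modular subset connects taxa of the same
module.  Comparing two conditions' edge sets classifies every edge as
disease-only, control-only, or shared.

A taxon is *influential* if removing it from its intra-modular
neighbourhood significantly shifts the remaining nodes' centralities:
normalized degree, normalized closeness (Wasserman-Faust per-component
convention), and local transitivity are computed with and without the
taxon, and each metric's paired differences are tested with a two-sided
Wilcoxon signed-rank test (exact distribution up to 25 informative pairs,
normal approximation with continuity correction above).  Per taxon, the
three p-values are BH-adjusted; any q <= 0.05 flags the taxon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .sparcc import CorrelationEstimate, bh_adjust

__all__ = [
    "EdgeList",
    "EdgeClassification",
    "InfluenceReport",
    "intra_modular_edges",
    "classify_edges",
    "centrality_metrics",
    "wilcoxon_signed_rank",
    "influential_taxa",
    "annotate_da",
]

logger = logging.getLogger(__name__)


@dataclass
class EdgeList:
    """Filtered correlation edges for one condition.

    edges: DataFrame (taxon_a, taxon_b, r, q, same_module) with
    taxon_a < taxon_b lexicographically; r_min/q_max record the filters.
    """

    edges: pd.DataFrame
    condition: str = ""
    r_min: float = 0.2
    q_max: float = 0.05

    def __post_init__(self) -> None:
        if len(self.edges):
            if (self.edges["r"] < self.r_min - 1e-12).any():
                raise ValueError("edge below the r_min filter")
            if (self.edges["q"] > self.q_max + 1e-12).any():
                raise ValueError("edge above the q_max filter")
            bad = self.edges["taxon_a"] >= self.edges["taxon_b"]
            if bad.any():
                raise ValueError("edges must satisfy taxon_a < taxon_b")

    def same_module_only(self) -> "EdgeList":
        return EdgeList(
            edges=self.edges[self.edges["same_module"].astype(bool)].reset_index(drop=True),
            condition=self.condition,
            r_min=self.r_min,
            q_max=self.q_max,
        )

    def pairs(self) -> set:
        return set(zip(self.edges["taxon_a"], self.edges["taxon_b"]))


@dataclass
class EdgeClassification:
    """Union of two conditions' edges, partitioned by origin."""

    table: pd.DataFrame  # taxon_a, taxon_b, edge_class, r_A, r_B

    def counts(self) -> dict:
        return self.table["edge_class"].value_counts().to_dict()


@dataclass
class InfluenceReport:
    """Per-taxon leave-one-out centrality test results."""

    table: pd.DataFrame
    q_threshold: float = 0.05


def intra_modular_edges(
    corr: CorrelationEstimate,
    labels,
    r_min: float = 0.2,
    q_max: float = 0.05,
    condition: str = "",
) -> EdgeList:
    """Edges with r >= r_min and q <= q_max, flagged by module co-membership.

    Label-0 (unassigned) taxa always carry same_module = False.
    """
    if corr.taxa is None:
        raise ValueError("CorrelationEstimate needs taxon names for edge lists")
    taxa = list(corr.taxa)
    labels = np.asarray(labels)
    if labels.size != len(taxa):
        raise ValueError("labels must cover the correlation matrix's taxa")
    n = len(taxa)
    iu, ju = np.triu_indices(n, k=1)
    r = corr.r[iu, ju]
    q = corr.q[iu, ju]
    keep = (r >= r_min) & (q <= q_max)
    rows = []
    for i, j, rv, qv in zip(iu[keep], ju[keep], r[keep], q[keep]):
        a, b = taxa[i], taxa[j]
        if a > b:
            a, b = b, a
        same = labels[i] == labels[j] and labels[i] != 0
        rows.append({"taxon_a": a, "taxon_b": b, "r": rv, "q": qv, "same_module": bool(same)})
    edges = pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "r", "q", "same_module"])
    return EdgeList(edges=edges, condition=condition, r_min=r_min, q_max=q_max)


def classify_edges(edges_a: EdgeList, edges_b: EdgeList) -> EdgeClassification:
    """Partition the union of two edge sets: A-only / B-only / shared.

    Condition A is conventionally the disease, B the control, matching
    the blue/red/gray colouring of two-condition network plots.
    """
    pa = edges_a.pairs()
    pb = edges_b.pairs()
    ra = dict(zip(zip(edges_a.edges["taxon_a"], edges_a.edges["taxon_b"]), edges_a.edges["r"]))
    rb = dict(zip(zip(edges_b.edges["taxon_a"], edges_b.edges["taxon_b"]), edges_b.edges["r"]))
    rows = []
    for pair in sorted(pa | pb):
        if pair in pa and pair in pb:
            cls = "shared"
        elif pair in pa:
            cls = "disease_only"
        else:
            cls = "control_only"
        rows.append(
            {
                "taxon_a": pair[0],
                "taxon_b": pair[1],
                "edge_class": cls,
                "r_A": ra.get(pair, np.nan),
                "r_B": rb.get(pair, np.nan),
            }
        )
    return EdgeClassification(
        table=pd.DataFrame(
            rows, columns=["taxon_a", "taxon_b", "edge_class", "r_A", "r_B"]
        )
    )


def centrality_metrics(graph: nx.Graph) -> pd.DataFrame:
    """Normalized degree, normalized closeness, local transitivity per node.

    degree_n = deg/(n-1); closeness follows the Wasserman-Faust
    per-component convention (scaled by the reachable fraction), so nodes
    in singleton components get 0; local transitivity is the fraction of
    closed triads through the node, 0 when degree < 2.
    """
    n = graph.number_of_nodes()
    if n < 2:
        logger.warning("graph has < 2 nodes; all centralities set to 0")
        return pd.DataFrame(
            {"degree_n": 0.0, "closeness_n": 0.0, "transitivity_local": 0.0},
            index=list(graph.nodes),
        )
    degree = {v: d / (n - 1) for v, d in graph.degree()}
    closeness = nx.closeness_centrality(graph, wf_improved=True)
    transitivity = nx.clustering(graph)
    return pd.DataFrame(
        {
            "degree_n": pd.Series(degree),
            "closeness_n": pd.Series(closeness),
            "transitivity_local": pd.Series(transitivity),
        }
    ).loc[list(graph.nodes)]


def wilcoxon_signed_rank(differences, exact_max_n: int = 25) -> float:
    """Two-sided Wilcoxon signed-rank p for a paired difference vector.

    Zero differences are discarded; fewer than one informative pair gives
    p = 1.  Exact distribution for n <= ``exact_max_n``, else the normal
    approximation with continuity correction.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    if d.size < 1:
        return 1.0
    method = "exact" if d.size <= exact_max_n else "approx"
    try:
        res = stats.wilcoxon(d, alternative="two-sided", method=method, correction=True)
    except ValueError:
        res = stats.wilcoxon(d, alternative="two-sided", method="approx", correction=True)
    return float(res.pvalue)


def _module_members(taxon: str, taxa: list, labels: np.ndarray) -> set:
    pos = {t: i for i, t in enumerate(taxa)}
    if taxon not in pos:
        return set()
    lab = labels[pos[taxon]]
    if lab == 0:
        return set()
    return {t for t, i in pos.items() if labels[i] == lab}


def influential_taxa(
    edges_a: EdgeList,
    taxa_a: list,
    labels_a,
    edges_b: EdgeList,
    taxa_b: list,
    labels_b,
    q_threshold: float = 0.05,
    min_pairs: int = 5,
    mode: str = "union",
) -> InfluenceReport:
    """Leave-one-out centrality test for every module-assigned taxon.

    For each candidate taxon t (assigned a non-zero module in either
    condition), the evaluation graph is the union of both conditions'
    filtered intra-modular edges restricted to {t} + t's module members
    in A + t's module members in B (``mode="union"``; ``"A"``/``"B"``
    restrict to one condition's edges).  Metrics are computed with t and
    with t removed; for each metric a paired two-sided Wilcoxon
    signed-rank over the remaining nodes' changes yields a p-value; the
    three p-values are BH-adjusted per taxon and any q <= ``q_threshold``
    flags the taxon as influential.  Fewer than ``min_pairs`` non-zero
    differences across all metrics marks the taxon underpowered (p = 1).
    """
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    intra_a = edges_a.same_module_only()
    intra_b = edges_b.same_module_only()
    if mode == "union":
        frames = [e for e in (intra_a.edges, intra_b.edges) if len(e)]
        edge_pool = (
            pd.concat(frames, ignore_index=True) if frames else intra_a.edges
        )
    elif mode == "A":
        edge_pool = intra_a.edges
    elif mode == "B":
        edge_pool = intra_b.edges
    else:
        raise ValueError("mode must be 'union', 'A' or 'B'")

    candidates = sorted(
        {t for t, l in zip(taxa_a, labels_a) if l != 0}
        | {t for t, l in zip(taxa_b, labels_b) if l != 0}
    )
    rows = []
    metrics = ("degree_n", "closeness_n", "transitivity_local")
    for t in candidates:
        nodes = (
            {t}
            | _module_members(t, list(taxa_a), labels_a)
            | _module_members(t, list(taxa_b), labels_b)
        )
        sub = edge_pool[
            edge_pool["taxon_a"].isin(nodes) & edge_pool["taxon_b"].isin(nodes)
        ]
        g = nx.Graph()
        g.add_nodes_from(sorted(nodes))
        g.add_edges_from(zip(sub["taxon_a"], sub["taxon_b"]))
        others = [v for v in g.nodes if v != t]
        if not others:
            continue
        with_t = centrality_metrics(g).loc[others]
        # "removal" strips t's incident edges but keeps the node universe, so
        # the (n-1) normalisations stay on a common scale and an edge-less
        # taxon is an exact null (no metric moves)
        g_wo = g.copy()
        g_wo.remove_edges_from(list(g.edges(t)))
        without_t = centrality_metrics(g_wo).loc[others]
        diffs = {m: (with_t[m] - without_t[m]).to_numpy() for m in metrics}
        # a metric with too few informative pairs is untestable: p = 1
        pvals = {}
        informative = {}
        for m in metrics:
            informative[m] = int((diffs[m] != 0).sum())
            pvals[m] = (
                wilcoxon_signed_rank(diffs[m]) if informative[m] >= min_pairs else 1.0
            )
        underpowered = all(v < min_pairs for v in informative.values())
        qvals = bh_adjust(np.array([pvals[m] for m in metrics]))
        rows.append(
            {
                "taxon": t,
                "n_neighbors": len(others),
                "module_A": _label_of(t, taxa_a, labels_a),
                "module_B": _label_of(t, taxa_b, labels_b),
                **{f"p_{m}": pvals[m] for m in metrics},
                **{f"q_{m}": q for m, q in zip(metrics, qvals)},
                "underpowered": underpowered,
                "influential": bool((qvals <= q_threshold).any()),
            }
        )
    table = pd.DataFrame(rows)
    return InfluenceReport(table=table, q_threshold=q_threshold)


def _label_of(taxon: str, taxa, labels) -> int:
    taxa = list(taxa)
    if taxon in taxa:
        return int(np.asarray(labels)[taxa.index(taxon)])
    return 0


def annotate_da(report: InfluenceReport, da_tables) -> pd.DataFrame:
    """Left-join user-supplied differential-abundance flags onto the report.

    Each DA table needs columns (taxon, level, method, significant); one
    boolean column per method is added (NA where the method did not test
    the taxon).  DA is never recomputed here.
    """
    out = report.table.copy()
    if not isinstance(da_tables, (list, tuple)):
        da_tables = [da_tables]
    for da in da_tables:
        required = {"taxon", "level", "method", "significant"}
        missing = required - set(da.columns)
        if missing:
            raise ValueError(f"DA table missing columns: {sorted(missing)}")
        dup = da.duplicated(subset=["taxon", "method"], keep=False)
        if dup.any():
            offenders = da.loc[dup, ["taxon", "method"]].drop_duplicates()
            raise ValueError(
                f"duplicate (taxon, method) rows in DA table: {offenders.to_dict('records')}"
            )
        known = set(out["taxon"]) if len(out) else set()
        unknown = sorted(set(da["taxon"]) - known)
        if unknown:
            logger.warning("DA table has taxa absent from the report: %s", unknown)
        for method, sub in da.groupby("method"):
            col = f"{method}_significant"
            mapping = dict(zip(sub["taxon"], sub["significant"]))
            out[col] = out["taxon"].map(mapping)
    return out
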
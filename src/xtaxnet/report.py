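"""Static report artifacts: plots and GraphML exports.

These replace interactive exploration with files a user can open or load
into Cytoscape/Gephi: the pattern-colour grid of the min-size sweep, the
silhouette curve, the consensus heatmap, the medianRank-vs-Z_summary
scatter, classified-edge GraphML, and per-taxon log2 abundance plots.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "plot_pattern_grid",
    "plot_silhouette_curve",
    "plot_consensus_heatmap",
    "plot_preservation_scatter",
    "plot_log2_abundance",
    "edges_to_graphml",
]


def plot_pattern_grid(sweep, path) -> None:
    """Taxa x min_size grid coloured by module label (0 = unassigned)."""
    mat = np.column_stack([sweep.labels[m] for m in sweep.min_sizes])
    fig, ax = plt.subplots(figsize=(0.22 * len(sweep.min_sizes) + 2, 6))
    ax.imshow(mat, aspect="auto", cmap="tab20", interpolation="nearest")
    ax.set_xticks(range(len(sweep.min_sizes)))
    ax.set_xticklabels(sweep.min_sizes, fontsize=6, rotation=90)
    dup = [i for i, m in enumerate(sweep.min_sizes) if not sweep.is_unique[m]]
    for i in dup:
        ax.axvspan(i - 0.5, i + 0.5, color="black", alpha=0.25)
    ax.set_xlabel("minimal taxa per module")
    ax.set_ylabel("taxa")
    ax.set_title("Module patterns (shaded = duplicate pattern)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_silhouette_curve(solution, path) -> None:
    ks = sorted(solution.silhouette_curve)
    vals = [solution.silhouette_curve[k] for k in ks]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(ks, vals, marker="o")
    if solution.k_opt is not None:
        ax.axvline(solution.k_opt, color="red", ls="--", label=f"k_opt = {solution.k_opt}")
        ax.legend()
    ax.set_xlabel("number of modules k")
    ax.set_ylabel("average silhouette width")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_consensus_heatmap(cons, path, labels=None) -> None:
    c = cons.C
    if labels is not None:
        order = np.argsort(labels)
        c = c[np.ix_(order, order)]
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(c, cmap="viridis", vmin=0, vmax=1, interpolation="nearest")
    fig.colorbar(im, ax=ax, label="consensus")
    ax.set_title(f"Consensus over {cons.n_patterns} patterns")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_preservation_scatter(stats_table: pd.DataFrame, path, title="") -> None:
    """medianRank vs Z_summary, node size = module size."""
    tbl = stats_table.replace([np.inf, -np.inf], np.nan).dropna(subset=["Z_summary"])
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(
        tbl["medianRank"], tbl["Z_summary"], s=tbl["size"] * 8, alpha=0.7,
        edgecolor="black",
    )
    for mod, row in tbl.iterrows():
        ax.annotate(str(mod), (row["medianRank"], row["Z_summary"]), fontsize=8)
    ax.axhline(2, color="gray", ls=":", lw=1)
    ax.axhline(10, color="gray", ls="--", lw=1)
    ax.set_xlabel("medianRank (lower = more preserved)")
    ax.set_ylabel("Z_summary (higher = more preserved)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_log2_abundance(stacked_a, stacked_b, taxon_id: str, path) -> None:
    """Per-condition log2(count + 1) distributions for one taxon."""
    fig, ax = plt.subplots(figsize=(5, 4))
    data = []
    labels = []
    for stk in (stacked_a, stacked_b):
        if taxon_id in stk.counts.columns:
            data.append(np.log2(stk.counts[taxon_id].to_numpy() + 1.0))
            labels.append(stk.condition_label or "?")
    if not data:
        raise KeyError(f"taxon {taxon_id!r} absent from both conditions")
    ax.boxplot(data, tick_labels=labels)
    ax.set_ylabel("log2(count + 1)")
    ax.set_title(taxon_id)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def edges_to_graphml(classification, path, node_attrs: pd.DataFrame | None = None) -> None:
    """Classified edges as GraphML (edge attrs: edge_class, r_A, r_B)."""
    g = nx.Graph()
    for _, row in classification.table.iterrows():
        g.add_edge(
            row["taxon_a"],
            row["taxon_b"],
            edge_class=row["edge_class"],
            r_A=float(row["r_A"]) if pd.notna(row["r_A"]) else 0.0,
            r_B=float(row["r_B"]) if pd.notna(row["r_B"]) else 0.0,
        )
    if node_attrs is not None:
        for node in g.nodes:
            if node in node_attrs.index:
                for col, val in node_attrs.loc[node].items():
                    g.nodes[node][col] = (
                        val if isinstance(val, (int, float, bool)) else str(val)
                    )
    nx.write_graphml(g, path)
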
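"""Consensus-based module determination from the TOM dissimilarity.

One complete-linkage dendrogram is built from 1 - TOM and cut with a
range of minimal module sizes (3..40 by default).  Each cut yields a
partition; duplicate partitions (identical up to label permutation) are
flagged, and the unique patterns with at least ``min_modules`` modules are
combined by the cluster-based similarity partitioning algorithm (CSPA):
average the binary co-membership matrices into a consensus matrix C.

The module count is then chosen on C: candidate cuts k = 2..k_max of the
consensus dissimilarity 1 - C are scored by (a) the per-module proportion
of zero consensus entries, which must stay below 10%, and (b) the average
silhouette width, taking the first local maximum (the point just before
the first drop).

Label 0 is reserved for unassigned taxa throughout: they are co-members
of nothing, including each other — counting them as one module would
fabricate consensus among unrelated taxa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import complete, fcluster
from scipy.spatial.distance import squareform

__all__ = [
    "PatternSweep",
    "ConsensusMatrix",
    "ModuleSolution",
    "cut_tree_min_size",
    "sweep_module_patterns",
    "select_patterns",
    "consensus_matrix",
    "silhouette_samples_precomputed",
    "average_silhouette",
    "silhouette_curve",
    "optimal_modules",
    "find_modules",
]


@dataclass
class PatternSweep:
    """Partitions of the taxa over a sweep of minimal module sizes.

    labels[min_size] is a full taxa -> module-label vector (0 = unassigned);
    n_modules counts non-zero modules; is_unique flags the first occurrence
    of each distinct partition (compared by co-membership, hence invariant
    to relabeling).
    """

    min_sizes: list
    labels: dict
    n_modules: dict
    is_unique: dict
    linkage: np.ndarray | None = None

    def unique_min_sizes(self) -> list:
        return [m for m in self.min_sizes if self.is_unique[m]]


@dataclass
class ConsensusMatrix:
    """CSPA consensus: mean of binary co-membership matrices."""

    C: np.ndarray
    patterns_used: list
    n_patterns: int

    def __post_init__(self) -> None:
        if not np.allclose(self.C, self.C.T, atol=1e-12):
            raise ValueError("consensus matrix must be symmetric")
        if np.any((self.C < -1e-12) | (self.C > 1 + 1e-12)):
            raise ValueError("consensus entries must lie in [0, 1]")


@dataclass
class ModuleSolution:
    """Chosen module count with its labels and selection diagnostics."""

    k_opt: int | None
    labels: np.ndarray | None
    silhouette_curve: dict
    zero_proportion: dict
    labels_per_k: dict = field(default_factory=dict)
    selection_mode: str = "auto"


def _comembership(labels: np.ndarray) -> np.ndarray:
    """Binary co-membership; label-0 taxa are co-members of nothing."""
    lab = np.asarray(labels)
    same = lab[:, None] == lab[None, :]
    nonzero = lab != 0
    return (same & nonzero[:, None] & nonzero[None, :]).astype(float)


def cut_tree_min_size(
    linkage_matrix: np.ndarray,
    min_size: int,
    dissim: np.ndarray,
    height_fraction: float = 0.5,
) -> np.ndarray:
    """Tree-variant dynamic cut honouring a minimum module size.

    The dendrogram is first cut statically at ``height_fraction`` of the
    merge-height range (branches joining above that height stay separate).
    Clusters smaller than ``min_size`` are then merged into their nearest
    cluster by complete-linkage distance, repeatedly, so that the final
    partition respects the size floor while still following the tree —
    this is what makes the partition genuinely change as ``min_size``
    sweeps upward.  Only if a single undersized cluster is left with no
    partner does it fall to the reserved unassigned label 0.  Modules are
    relabelled 1..k in decreasing size order (ties by first leaf), so
    labels are deterministic.
    """
    heights = linkage_matrix[:, 2]
    lo, hi = float(heights.min()), float(heights.max())
    cut_h = lo + height_fraction * (hi - lo)
    raw = fcluster(linkage_matrix, t=cut_h, criterion="distance")
    clusters = [np.nonzero(raw == lab)[0] for lab in np.unique(raw)]

    def complete_distance(u: np.ndarray, v: np.ndarray) -> float:
        return float(dissim[np.ix_(u, v)].max())

    while len(clusters) > 1:
        sizes = np.array([c.size for c in clusters])
        small = np.nonzero(sizes < min_size)[0]
        if small.size == 0:
            break
        # merge the smallest undersized cluster into its nearest cluster
        u = small[np.argmin(sizes[small])]
        dists = [
            complete_distance(clusters[u], clusters[v]) if v != u else np.inf
            for v in range(len(clusters))
        ]
        v = int(np.argmin(dists))
        merged = np.sort(np.concatenate([clusters[u], clusters[v]]))
        clusters = [c for i, c in enumerate(clusters) if i not in (u, v)] + [merged]

    labels = np.zeros_like(raw)
    keyed = sorted(
        (c for c in clusters if c.size >= min_size),
        key=lambda c: (-c.size, int(c[0])),
    )
    for new_lab, members in enumerate(keyed, start=1):
        labels[members] = new_lab
    return labels


def sweep_module_patterns(
    dissim: np.ndarray,
    min_sizes=range(3, 41),
    height_fraction: float = 0.5,
) -> PatternSweep:
    """Complete-linkage dendrogram cut over a range of minimal module sizes."""
    dissim = np.asarray(dissim, dtype=float)
    n = dissim.shape[0]
    if n < 3:
        raise ValueError("need at least 3 taxa to sweep module patterns")
    if not np.allclose(dissim, dissim.T, atol=1e-10):
        raise ValueError("dissimilarity must be symmetric")
    if not np.allclose(np.diag(dissim), 0.0):
        raise ValueError("dissimilarity must have a zero diagonal")
    z = complete(squareform(dissim, checks=False))
    min_sizes = list(min_sizes)
    labels: dict = {}
    n_modules: dict = {}
    is_unique: dict = {}
    seen: list[tuple[np.ndarray, int]] = []  # (comembership, representative min_size)
    for ms in min_sizes:
        lab = cut_tree_min_size(z, ms, dissim, height_fraction)
        labels[ms] = lab
        n_modules[ms] = int(len(set(lab) - {0}))
        com = _comembership(lab)
        dup = any(np.array_equal(com, prev) for prev, _ in seen)
        is_unique[ms] = not dup
        if not dup:
            seen.append((com, ms))
    return PatternSweep(
        min_sizes=min_sizes,
        labels=labels,
        n_modules=n_modules,
        is_unique=is_unique,
        linkage=z,
    )


def select_patterns(
    sweep: PatternSweep,
    min_modules: int = 10,
    manual=None,
) -> list:
    """Unique patterns with >= ``min_modules`` modules (or a manual list)."""
    if manual is not None:
        manual = list(manual)
        missing = [m for m in manual if m not in sweep.labels]
        if missing:
            raise ValueError(f"manual min_sizes not in sweep: {missing}")
        if not manual:
            raise ValueError("manual pattern list is empty")
        return manual
    chosen = [
        m
        for m in sweep.min_sizes
        if sweep.is_unique[m] and sweep.n_modules[m] >= min_modules
    ]
    if not chosen:
        raise ValueError(
            f"no unique pattern has >= {min_modules} modules; "
            "lower min_modules or select patterns manually"
        )
    return chosen


def consensus_matrix(sweep: PatternSweep, selected) -> ConsensusMatrix:
    """CSPA: average the selected patterns' binary co-membership matrices."""
    selected = list(selected)
    if not selected:
        raise ValueError("no patterns selected")
    mats = [_comembership(sweep.labels[m]) for m in selected]
    c = np.mean(mats, axis=0)
    np.fill_diagonal(c, 1.0)
    return ConsensusMatrix(C=c, patterns_used=selected, n_patterns=len(selected))


def silhouette_samples_precomputed(dissim: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-sample silhouette widths s(i) = (b - a)/max(a, b) on a
    precomputed dissimilarity; members of singleton clusters get 0."""
    d = np.asarray(dissim, dtype=float)
    lab = np.asarray(labels)
    n = d.shape[0]
    uniq = np.unique(lab)
    if uniq.size < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    s = np.zeros(n)
    masks = {u: lab == u for u in uniq}
    sizes = {u: int(m.sum()) for u, m in masks.items()}
    for i in range(n):
        own = lab[i]
        if sizes[own] == 1:
            continue  # singleton convention: s(i) = 0
        a = d[i, masks[own]].sum() / (sizes[own] - 1)
        b = min(
            d[i, masks[u]].mean() for u in uniq if u != own
        )
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return s


def average_silhouette(dissim: np.ndarray, labels: np.ndarray) -> float:
    return float(silhouette_samples_precomputed(dissim, labels).mean())


def _zero_proportions(c: np.ndarray, labels: np.ndarray) -> dict:
    """Per-module fraction of exactly-zero consensus entries in the
    module's off-diagonal block (empty block -> 0)."""
    out = {}
    for u in np.unique(labels):
        idx = np.nonzero(labels == u)[0]
        m = idx.size
        if m < 2:
            out[int(u)] = 0.0
            continue
        block = c[np.ix_(idx, idx)]
        offdiag = m * m - m
        out[int(u)] = float((block == 0).sum() - (np.diag(block) == 0).sum()) / offdiag
    return out


def silhouette_curve(cons: ConsensusMatrix, k_range=None) -> ModuleSolution:
    """Average silhouette width and zero-proportions for each candidate k.

    The consensus dissimilarity 1 - C is clustered by complete linkage and
    cut into exactly k clusters for k in ``k_range`` (default 2..k_max
    where k_max is the largest achievable distinct-cluster count).
    """
    c = cons.C
    n = c.shape[0]
    d = 1.0 - c
    np.fill_diagonal(d, 0.0)
    z = complete(squareform(d, checks=False))
    if k_range is None:
        k_range = range(2, n)
    sil: dict = {}
    zp: dict = {}
    labels_per_k: dict = {}
    for k in k_range:
        if k > n:
            warnings.warn(f"k={k} exceeds the number of taxa; skipped", stacklevel=2)
            continue
        lab = fcluster(z, t=k, criterion="maxclust")
        # zero-height ties can make k unachievable; the cut then repeats a
        # smaller k's partition and is not a distinct candidate
        if len(np.unique(lab)) != k:
            continue
        sil[k] = average_silhouette(d, lab)
        zp[k] = _zero_proportions(c, lab)
        labels_per_k[k] = lab
    return ModuleSolution(
        k_opt=None,
        labels=None,
        silhouette_curve=sil,
        zero_proportion=zp,
        labels_per_k=labels_per_k,
    )


def optimal_modules(
    solution: ModuleSolution,
    zero_prop_max: float = 0.10,
    manual_k: int | None = None,
) -> ModuleSolution:
    """Pick k: first local maximum of s(k) among zero-proportion-clean cuts.

    A cut passes the gate when every module's zero proportion is below
    ``zero_prop_max``.  Scanning gated candidates in ascending k, the
    chosen k satisfies s(k) >= s(k-1) and s(k) > s(k+1) against its curve
    neighbours, one-sided at the endpoints; ties prefer the smaller k.
    ``manual_k`` overrides the scan.
    """
    sil = solution.silhouette_curve
    if not sil:
        raise ValueError("silhouette curve is empty; run silhouette_curve first")
    ks = sorted(sil)
    if manual_k is not None:
        if manual_k not in solution.labels_per_k:
            raise ValueError(f"manual_k={manual_k} has no computed cut")
        return ModuleSolution(
            k_opt=manual_k,
            labels=solution.labels_per_k[manual_k],
            silhouette_curve=sil,
            zero_proportion=solution.zero_proportion,
            labels_per_k=solution.labels_per_k,
            selection_mode="manual",
        )
    gated = [
        k for k in ks if max(solution.zero_proportion[k].values()) < zero_prop_max
    ]
    if not gated:
        worst = {
            k: max(solution.zero_proportion[k].values()) for k in ks
        }
        raise ValueError(
            "no candidate k passes the zero-proportion gate "
            f"(< {zero_prop_max:.0%}); worst per k: {worst}"
        )
    k_opt = None
    for k in gated:
        # neighbours among the gated candidates (gating removes curve points)
        smaller = [x for x in gated if x < k]
        larger = [x for x in gated if x > k]
        prev_ok = (not smaller) or (sil[k] >= sil[smaller[-1]])
        # ties with the next candidate prefer the smaller k (parsimony)
        next_ok = (not larger) or (sil[k] >= sil[larger[0]])
        if prev_ok and next_ok:
            k_opt = k
            break
    if k_opt is None:
        k_opt = gated[-1]  # monotone rising curve: endpoint rule
    return ModuleSolution(
        k_opt=k_opt,
        labels=solution.labels_per_k[k_opt],
        silhouette_curve=sil,
        zero_proportion=solution.zero_proportion,
        labels_per_k=solution.labels_per_k,
        selection_mode="auto",
    )


def find_modules(
    dissim: np.ndarray,
    min_sizes=range(3, 41),
    min_modules: int = 10,
    zero_prop_max: float = 0.10,
    manual_patterns=None,
    manual_k: int | None = None,
    height_fraction: float = 0.5,
):
    """Convenience: sweep -> select -> consensus -> silhouette -> k_opt.

    Returns (sweep, consensus, solution).
    """
    sweep = sweep_module_patterns(dissim, min_sizes, height_fraction)
    selected = select_patterns(sweep, min_modules=min_modules, manual=manual_patterns)
    cons = consensus_matrix(sweep, selected)
    # candidate module counts are bounded by the granularity the selected
    # patterns actually propose
    k_max = max(sweep.n_modules[m] for m in selected)
    partial = silhouette_curve(cons, k_range=range(2, max(k_max, 2) + 1))
    solution = optimal_modules(partial, zero_prop_max=zero_prop_max, manual_k=manual_k)
    return sweep, cons, solution
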
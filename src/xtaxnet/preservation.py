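"""Permutation-based module preservation between two conditions.

Given the reference condition's modules, each module is scored in the
test condition by four correlation-network statistics:

  density:      meanCor  - mean intramodular test correlation
                meanAdj  - mean intramodular test adjacency
  connectivity: cor_kIM  - correlation of ref vs test intramodular
                           connectivity vectors
                cor_cor  - correlation of ref vs test intramodular
                           correlation entries

The null permutes module labels over the taxa shared by both conditions;
Z = (observed - null mean) / null sd per statistic, Z_density and
Z_connectivity are the medians of their pairs, and Z_summary their mean.
medianRank is the median over the four statistics of the module's rank
(descending) among all modules, less sensitive to module size than Z.
By convention Z_summary > 10 indicates strong preservation and < 2 none.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network_tom import signed_adjacency

__all__ = ["PreservationStats", "module_preservation", "shared_taxa_report"]

logger = logging.getLogger(__name__)

_STATS = ("meanCor", "meanAdj", "cor_kIM", "cor_cor")


@dataclass
class PreservationStats:
    """Per-module preservation table plus the permutation-null components.

    table: DataFrame indexed by module id with columns size, Z_density,
    Z_connectivity, Z_summary, medianRank, degenerate (True where a null
    sd was zero and the Z was set to +inf).
    component_stats: per module, per statistic: observed, null mean, null sd.
    """

    table: pd.DataFrame
    component_stats: dict
    n_permutations: int
    seed: int | None


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def _module_stats(
    idx: np.ndarray,
    r_ref: np.ndarray,
    r_test: np.ndarray,
    a_ref: np.ndarray,
    a_test: np.ndarray,
) -> dict:
    rr = r_ref[np.ix_(idx, idx)]
    rt = r_test[np.ix_(idx, idx)]
    ar = a_ref[np.ix_(idx, idx)]
    at = a_test[np.ix_(idx, idx)]
    m = idx.size
    iu = np.triu_indices(m, k=1)
    k_ref = ar.sum(axis=0) - 1.0  # intramodular connectivity
    k_test = at.sum(axis=0) - 1.0
    return {
        "meanCor": float(rt[iu].mean()),
        "meanAdj": float(at[iu].mean()),
        "cor_kIM": _pearson(k_ref, k_test),
        "cor_cor": _pearson(rr[iu], rt[iu]),
    }


def module_preservation(
    ref_taxa,
    labels_ref,
    r_ref: np.ndarray,
    test_taxa,
    r_test: np.ndarray,
    beta: float = 2.0,
    n_permutations: int = 100,
    seed: int | None = None,
    min_shared: int = 3,
) -> PreservationStats:
    """Preservation of the reference condition's modules in the test condition.

    ``ref_taxa`` / ``test_taxa`` are taxon-id sequences aligned with the
    correlation matrices; ``labels_ref`` assigns each reference taxon a
    module id (0 = unassigned, never evaluated).  Modules are reduced to
    the taxa present in both conditions; those with fewer than
    ``min_shared`` shared taxa are skipped with a warning.
    """
    ref_taxa = list(ref_taxa)
    test_taxa = list(test_taxa)
    labels_ref = np.asarray(labels_ref)
    if labels_ref.size != len(ref_taxa):
        raise ValueError("labels_ref must align with ref_taxa")
    pos_test = {t: i for i, t in enumerate(test_taxa)}
    shared = [t for t in ref_taxa if t in pos_test]
    if not shared:
        raise ValueError("conditions share no taxa")
    pos_ref = {t: i for i, t in enumerate(ref_taxa)}
    ref_idx = np.array([pos_ref[t] for t in shared])
    test_idx = np.array([pos_test[t] for t in shared])
    r_ref_s = r_ref[np.ix_(ref_idx, ref_idx)]
    r_test_s = r_test[np.ix_(test_idx, test_idx)]
    a_ref_s = signed_adjacency(r_ref_s, beta=beta)
    a_test_s = signed_adjacency(r_test_s, beta=beta)
    labels_shared = labels_ref[ref_idx]

    n_shared = len(shared)
    rows = []
    component: dict = {}
    module_ids = sorted(set(labels_shared) - {0})
    for mod in module_ids:
        members = np.nonzero(labels_shared == mod)[0]
        # permutation stream keyed to the module's membership (not its id),
        # so Z statistics are invariant to module relabeling
        digest = zlib.crc32(",".join(shared[i] for i in members).encode())
        rng = np.random.default_rng(
            np.random.SeedSequence([0 if seed is None else seed, digest])
        )
        if members.size < min_shared:
            logger.warning(
                "module %s has only %d shared taxa (< %d); skipped",
                mod,
                members.size,
                min_shared,
            )
            continue
        obs = _module_stats(members, r_ref_s, r_test_s, a_ref_s, a_test_s)
        null = {s: np.empty(n_permutations) for s in _STATS}
        size = members.size
        for b in range(n_permutations):
            perm = rng.permutation(n_shared)[:size]
            stats_b = _module_stats(perm, r_ref_s, r_test_s, a_ref_s, a_test_s)
            for s in _STATS:
                null[s][b] = stats_b[s]
        z = {}
        degenerate = False
        for s in _STATS:
            mu, sd = null[s].mean(), null[s].std(ddof=1)
            if sd < 1e-12:  # constant null (fp noise aside): Z undefined
                z[s] = np.inf if obs[s] > mu else (-np.inf if obs[s] < mu else 0.0)
                degenerate = True
            else:
                z[s] = (obs[s] - mu) / sd
        z_density = float(np.median([z["meanCor"], z["meanAdj"]]))
        z_connectivity = float(np.median([z["cor_kIM"], z["cor_cor"]]))
        rows.append(
            {
                "module": mod,
                "size": int(size),
                "Z_density": z_density,
                "Z_connectivity": z_connectivity,
                "Z_summary": (z_density + z_connectivity) / 2.0,
                "degenerate": degenerate,
            }
        )
        component[mod] = {
            s: {"observed": obs[s], "null_mean": float(null[s].mean()),
                "null_sd": float(null[s].std(ddof=1))}
            for s in _STATS
        }
    if not rows:
        raise ValueError("no module has enough shared taxa to evaluate")
    table = pd.DataFrame(rows).set_index("module")

    # medianRank over the four observed statistics, descending (1 = best);
    # degenerate modules are excluded from the ranking
    rankable = table.index[~table["degenerate"]]
    obs_df = pd.DataFrame(
        {s: {m: component[m][s]["observed"] for m in rankable} for s in _STATS}
    )
    if len(rankable):
        ranks = obs_df.rank(ascending=False, method="average")
        table.loc[rankable, "medianRank"] = ranks.median(axis=1)
    table.loc[table["degenerate"], "medianRank"] = np.nan
    return PreservationStats(
        table=table,
        component_stats=component,
        n_permutations=n_permutations,
        seed=seed,
    )


def shared_taxa_report(ref, test) -> pd.DataFrame:
    """Per-level counts (and lists) of shared and condition-specific taxa.

    ``ref`` and ``test`` are StackedTaxaMatrix objects; taxa are compared
    by (level, name).
    """
    rows = []
    ref_taxa = ref.taxa
    test_taxa = test.taxa
    levels = sorted(
        set(ref_taxa["level"]) | set(test_taxa["level"]),
        key=lambda lv: ("Phylum", "Class", "Order", "Family", "Genus", "Species").index(lv),
    )
    for level in levels:
        ref_names = set(ref_taxa.loc[ref_taxa["level"] == level, "name"])
        test_names = set(test_taxa.loc[test_taxa["level"] == level, "name"])
        rows.append(
            {
                "level": level,
                "shared": len(ref_names & test_names),
                "ref_only": len(ref_names - test_names),
                "test_only": len(test_names - ref_names),
                "shared_taxa": sorted(ref_names & test_names),
                "ref_only_taxa": sorted(ref_names - test_names),
                "test_only_taxa": sorted(test_names - ref_names),
            }
        )
    return pd.DataFrame(rows)
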
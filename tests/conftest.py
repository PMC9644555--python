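"""Shared fixtures: small profiles, planted correlation matrices, oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from xtaxnet import CorrelationEstimate, TaxonomicProfile
from xtaxnet.io_profiles import LEVELS


def block_correlation(n_taxa: int, blocks: dict, rho: float | None = None) -> np.ndarray:
    """Correlation matrix with planted blocks: {module_id: index list} or
    per-block rho via {module_id: (indices, rho)}."""
    r = np.zeros((n_taxa, n_taxa))
    for _, spec in blocks.items():
        if isinstance(spec, tuple):
            idx, block_rho = spec
        else:
            idx, block_rho = spec, rho
        idx = np.asarray(idx)
        r[np.ix_(idx, idx)] = block_rho
    np.fill_diagonal(r, 1.0)
    return r


def make_profile(
    n_samples: int = 6,
    n_features: int = 8,
    seed: int = 0,
    conditions=("CD", "control"),
) -> TaxonomicProfile:
    """Small random profile with a two-genus, two-phylum taxonomy."""
    rng = np.random.default_rng(seed)
    counts = pd.DataFrame(
        rng.integers(0, 50, size=(n_samples, n_features)),
        index=[f"S{i}" for i in range(n_samples)],
        columns=[f"ASV{i}" for i in range(n_features)],
    )
    tax = pd.DataFrame(index=counts.columns, columns=list(LEVELS), dtype=object)
    for i, fid in enumerate(counts.columns):
        phylum = f"Phy{i % 2}"
        genus = f"Gen{i % 4}"
        tax.loc[fid] = [phylum, f"Cls{i % 2}", f"Ord{i % 2}", f"Fam{i % 4}", genus, f"Sp{i}"]
    meta = pd.DataFrame(
        {"diagnosis": [conditions[i % 2] for i in range(n_samples)]},
        index=counts.index,
    )
    return TaxonomicProfile(counts=counts, taxonomy=tax, metadata=meta)


def corr_estimate(taxa, edge_values: dict, default_q: float = 1.0) -> CorrelationEstimate:
    """Hand-built CorrelationEstimate: edge_values maps (a, b) -> (r, q)."""
    taxa = list(taxa)
    n = len(taxa)
    pos = {t: i for i, t in enumerate(taxa)}
    r = np.zeros((n, n))
    q = np.full((n, n), default_q)
    for (a, b), (rv, qv) in edge_values.items():
        i, j = pos[a], pos[b]
        r[i, j] = r[j, i] = rv
        q[i, j] = q[j, i] = qv
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(q, 1.0)
    p = q.copy()
    return CorrelationEstimate(
        r=r, p=p, q=q, n_bootstraps=0, seed=None,
        basis_variances=np.ones(n), taxa=taxa,
    )


@pytest.fixture
def small_profile() -> TaxonomicProfile:
    return make_profile()


@pytest.fixture
def profile_trio_files(tmp_path):
    """TSV trio on disk for a 3-sample, 4-feature profile."""
    counts = pd.DataFrame(
        [[10, 0, 5, 3], [2, 8, 0, 7], [1, 1, 1, 1]],
        index=["S1", "S2", "S3"],
        columns=["ASV1", "ASV2", "ASV3", "ASV4"],
    )
    tax = pd.DataFrame(
        {
            "Phylum": ["p__Bacteroidota"] * 4,
            "Class": ["c__Bacteroidia"] * 4,
            "Order": ["o__Bacteroidales"] * 4,
            "Family": ["f__Bacteroidaceae", "f__Bacteroidaceae", "f__Tannerellaceae", "f__Tannerellaceae"],
            "Genus": ["g__Bacteroides", "g__Bacteroides", "g__Parabacteroides", "g__Parabacteroides"],
            "Species": ["s__fragilis", "s__ovatus", "s__distasonis", "s__merdae"],
        },
        index=["ASV1", "ASV2", "ASV3", "ASV4"],
    )
    meta = pd.DataFrame({"diagnosis": ["CD", "CD", "control"]}, index=["S1", "S2", "S3"])
    paths = {}
    for name, df in (("counts", counts.T), ("taxonomy", tax), ("metadata", meta)):
        path = tmp_path / f"{name}.tsv"
        df.to_csv(path, sep="\t")
        paths[name] = path
    return paths
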
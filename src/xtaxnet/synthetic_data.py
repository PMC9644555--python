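"""Synthetic compositional count data with planted co-occurrence structure.

The generative model is the one under which SparCC is consistent: each
sample draws latent basis log-abundances from a multivariate normal whose
correlation matrix contains planted blocks (co-occurring taxa groups);
observed fractions are the softmax of the log-abundances and counts are a
multinomial draw of those fractions at a lognormal sequencing depth.

Two-condition studies share a seed stream but use per-condition
substreams, so condition A's draws never depend on whether condition B is
generated.  Blocks carry a scope (``both``, ``A_only``, ``B_only``): out of
scope, the block's taxa are mutually independent, which is the planted
"condition-specific co-occurrence" that the preservation and
edge-classification stages are meant to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_profiles import LEVELS, TaxonomicProfile

__all__ = [
    "CorrelationBlock",
    "SyntheticSpec",
    "generate_taxonomy",
    "sample_compositional_counts",
    "generate_condition_counts",
    "generate_two_condition_study",
]

_SCOPES = ("both", "A_only", "B_only")


@dataclass
class CorrelationBlock:
    """A planted group of co-occurring species.

    species: species names (or species indices) forming the block;
    correlation: pairwise basis log-abundance correlation within the block;
    scope: which condition(s) the block is active in.
    """

    species: list
    correlation: float
    scope: str = "both"

    def __post_init__(self) -> None:
        if not -1.0 < self.correlation < 1.0:
            raise ValueError("block correlation must lie in (-1, 1)")
        if self.scope not in _SCOPES:
            raise ValueError(f"scope must be one of {_SCOPES}")


@dataclass
class SyntheticSpec:
    """Study conditions for the synthetic generator.

    fanout gives the number of phyla and then children per node at each
    subsequent rank (classes/phylum, ..., species/genus); the product is
    the species count.  Defaults emulate a small but realistic 16S study:
    150 samples per condition, 64 species over a balanced 6-level tree,
    unit log-normal basis variation and ~20k-read lognormal depths.
    """

    n_samples: int = 150
    fanout: tuple = (2, 2, 2, 2, 2, 2)
    blocks: list = field(default_factory=list)
    background_correlation: float = 0.0
    log_mean: float = 0.0
    log_sd: float = 1.0
    depth_log_mean: float = float(np.log(20000.0))
    depth_log_sd: float = 0.5
    condition_labels: tuple = ("A", "B")
    condition_column: str = "condition"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(f < 1 for f in self.fanout):
            raise ValueError("fanouts must be >= 1")
        if len(self.fanout) != 6:
            raise ValueError("fanout must give one branching factor per rank (6)")
        seen: set = set()
        for b in self.blocks:
            if seen & set(b.species):
                raise ValueError("blocks must be disjoint at species level")
            seen |= set(b.species)
        if self.depth_log_sd < 0 or self.depth_log_mean <= 0:
            raise ValueError("depth distribution parameters must be positive")

    @property
    def n_species(self) -> int:
        return int(np.prod(self.fanout))


def generate_taxonomy(spec: SyntheticSpec) -> pd.DataFrame:
    """Balanced 6-level taxonomy table, one row per species feature.

    Names encode the path (e.g. Genus "P1.C2.O1.F2.G1"), so species names
    are unique and every species has exactly one lineage.  Deterministic
    for a given spec (the tree has no random component).
    """
    prefixes = ("P", "C", "O", "F", "G", "S")
    rows = []
    idx = np.zeros(6, dtype=int)

    def recurse(depth: int, path: list) -> None:
        for k in range(spec.fanout[depth]):
            name = f"{prefixes[depth]}{k + 1}" if depth == 0 else f"{path[-1]}.{prefixes[depth]}{k + 1}"
            if depth == 5:
                rows.append(path + [name])
            else:
                recurse(depth + 1, path + [name])

    recurse(0, [])
    tax = pd.DataFrame(rows, columns=list(LEVELS))
    tax.index = [f"ASV{i + 1}" for i in range(len(tax))]
    tax.index.name = "feature_id"
    return tax


def _block_correlation_matrix(
    n_taxa: int,
    blocks: list,
    background: float,
    species_index: dict,
    active_scopes: tuple,
) -> np.ndarray:
    corr = np.full((n_taxa, n_taxa), background, dtype=float)
    np.fill_diagonal(corr, 1.0)
    for b in blocks:
        if b.scope not in active_scopes:
            continue
        idx = np.array([species_index[s] if not isinstance(s, (int, np.integer)) else int(s) for s in b.species])
        sub = np.full((idx.size, idx.size), b.correlation)
        np.fill_diagonal(sub, 1.0)
        corr[np.ix_(idx, idx)] = sub
    return corr


def sample_compositional_counts(
    correlation: np.ndarray,
    n_samples: int,
    rng: np.random.Generator,
    log_mean: float = 0.0,
    log_sd: float = 1.0,
    depth_log_mean: float = float(np.log(20000.0)),
    depth_log_sd: float = 0.5,
    block_name: str = "correlation matrix",
) -> np.ndarray:
    """Counts from the lognormal-basis + multinomial observation model.

    Raises if ``correlation`` is not positive definite (naming the
    offending block when called from the block-structured generator).
    """
    p = correlation.shape[0]
    cov = (log_sd**2) * correlation
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"non-positive-definite covariance for {block_name}") from exc
    z = rng.standard_normal((n_samples, p))
    log_abund = log_mean + z @ chol.T
    # softmax per sample: fractions carry only relative information
    log_abund -= log_abund.max(axis=1, keepdims=True)
    frac = np.exp(log_abund)
    frac /= frac.sum(axis=1, keepdims=True)
    depths = np.maximum(
        1, np.round(rng.lognormal(depth_log_mean, depth_log_sd, size=n_samples))
    ).astype(int)
    counts = np.empty((n_samples, p), dtype=np.int64)
    for s in range(n_samples):
        counts[s] = rng.multinomial(depths[s], frac[s])
    return counts


def _condition_rng(spec: SyntheticSpec, condition: str) -> np.random.Generator:
    # per-condition substream: generating B never perturbs A's draws
    idx = spec.condition_labels.index(condition)
    return np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(2)[idx])


def generate_condition_counts(spec: SyntheticSpec, condition: str) -> TaxonomicProfile:
    """One condition's TaxonomicProfile under the planted-block model."""
    if condition not in spec.condition_labels:
        raise ValueError(f"unknown condition {condition!r}; spec has {spec.condition_labels}")
    taxonomy = generate_taxonomy(spec)
    species_index = {name: i for i, name in enumerate(taxonomy["Species"])}
    is_a = condition == spec.condition_labels[0]
    active = ("both", "A_only") if is_a else ("both", "B_only")
    # validate PD per block before assembling (names the offender)
    for b in spec.blocks:
        size = len(b.species)
        if size > 1 and b.correlation <= -1.0 / (size - 1):
            raise ValueError(
                f"block {b.species[:3]}... correlation {b.correlation} is not "
                "positive definite for its size"
            )
    corr = _block_correlation_matrix(
        spec.n_species, spec.blocks, spec.background_correlation, species_index, active
    )
    rng = _condition_rng(spec, condition)
    counts = sample_compositional_counts(
        corr,
        spec.n_samples,
        rng,
        spec.log_mean,
        spec.log_sd,
        spec.depth_log_mean,
        spec.depth_log_sd,
    )
    sample_ids = [f"{condition}_S{i + 1}" for i in range(spec.n_samples)]
    counts_df = pd.DataFrame(counts, index=sample_ids, columns=taxonomy.index)
    metadata = pd.DataFrame({spec.condition_column: condition}, index=sample_ids)
    metadata.index.name = "sample_id"
    return TaxonomicProfile(counts=counts_df, taxonomy=taxonomy, metadata=metadata)


def generate_two_condition_study(spec: SyntheticSpec):
    """Both conditions from one spec and one seed stream.

    Shared blocks have identical correlation structure in A and B (but
    independent sample draws); scoped blocks are active only in their
    condition.
    """
    a = generate_condition_counts(spec, spec.condition_labels[0])
    b = generate_condition_counts(spec, spec.condition_labels[1])
    return a, b
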
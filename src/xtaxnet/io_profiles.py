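"""Taxonomic profile ingestion and stacked-taxa count matrices.

A 16S study arrives as three tables: a feature (ASV/OTU) count matrix, a
taxonomy table assigning each feature to the six canonical ranks
(Phylum ... Species), and per-sample metadata carrying the condition
labels.  The pipeline's working object is the *stacked-taxa matrix*: for
each rank, feature counts are summed into their assignments, the per-rank
tables are concatenated column-wise, and rare taxa (present in fewer than
10% of samples by default) are removed.  Analysing all ranks jointly keeps
parent-child abundance relationships in the network instead of committing
to a single resolution.

Counts stay raw integers throughout: no rarefaction, no normalisation —
the downstream correlation stage consumes raw compositional counts.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LEVELS",
    "LEVEL_PREFIXES",
    "TaxonomicProfile",
    "StackedTaxaMatrix",
    "read_profile",
    "filter_samples_by_depth",
    "subset_condition",
    "build_stacked_matrix",
]

logger = logging.getLogger(__name__)

LEVELS = ("Phylum", "Class", "Order", "Family", "Genus", "Species")
LEVEL_PREFIXES = {
    "Phylum": "p",
    "Class": "c",
    "Order": "o",
    "Family": "f",
    "Genus": "g",
    "Species": "s",
}

# SILVA/QIIME2-style rank prefixes: d__, k__, p__, c__, o__, f__, g__, s__
_RANK_PREFIX = re.compile(r"^\s*[dkpcofgs]__\s*")
_MISSING_TOKENS = {"", "na", "nan", "none", "unassigned", "unclassified", "uncultured"}


@dataclass
class TaxonomicProfile:
    """Counts + taxonomy + metadata for one study (or one condition).

    counts: samples x features non-negative integer DataFrame;
    taxonomy: features x rank DataFrame (subset of LEVELS, NaN allowed);
    metadata: samples x key DataFrame including the condition column.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dup}")
        if self.counts.columns.has_duplicates:
            dup = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dup}")
        if (np.asarray(self.counts) < 0).any():
            raise ValueError("counts must be non-negative")
        missing_tax = self.counts.columns.difference(self.taxonomy.index)
        if len(missing_tax):
            raise ValueError(
                f"features present in counts but absent from taxonomy: {sorted(missing_tax)}"
            )
        sym_diff = set(self.counts.index) ^ set(self.metadata.index)
        if sym_diff:
            raise ValueError(
                f"sample sets of counts and metadata differ: {sorted(sym_diff)}"
            )
        bad_levels = [c for c in self.taxonomy.columns if c not in LEVELS]
        if bad_levels:
            raise ValueError(f"unknown taxonomy ranks: {bad_levels}")
        # align row orders with counts
        self.metadata = self.metadata.loc[self.counts.index]
        self.taxonomy = self.taxonomy.loc[self.counts.columns]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.columns)

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=1)


@dataclass
class StackedTaxaMatrix:
    """Prevalence-filtered, rank-aggregated taxa stacked across Phylum...Species.

    counts: samples x stacked-taxa integer DataFrame (columns are taxon_ids
    of the form ``g__Bacteroides``); taxa: per-column records with columns
    (taxon_id, level, name, lineage); provenance: the filter settings used.
    """

    counts: pd.DataFrame
    taxa: pd.DataFrame
    condition_label: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.taxa["taxon_id"]):
            raise ValueError("stacked counts columns must match taxa table order")
        pairs = list(zip(self.taxa["level"], self.taxa["name"]))
        if len(pairs) != len(set(pairs)):
            raise ValueError("(level, name) pairs must be unique in a stacked matrix")
        unknown = set(self.taxa["level"]) - set(LEVELS)
        if unknown:
            raise ValueError(f"unknown levels in taxa table: {sorted(unknown)}")

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    def write(self, counts_path, taxa_path) -> None:
        """Stacked matrix as TSV plus the companion taxa table."""
        self.counts.to_csv(counts_path, sep="\t")
        self.taxa.to_csv(taxa_path, sep="\t", index=False)


def _strip_rank_prefix(value) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    name = _RANK_PREFIX.sub("", str(value)).strip()
    if name.lower() in _MISSING_TOKENS:
        return None
    return name


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def _read_biom_json(path: Path) -> pd.DataFrame:
    """Minimal reader for the BIOM 1.0 JSON dialect (dense or sparse)."""
    with open(path) as fh:
        doc = json.load(fh)
    obs_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    shape = tuple(doc["shape"])
    mat = np.zeros(shape)
    if doc.get("matrix_type") == "dense":
        mat[:] = np.asarray(doc["data"])
    else:
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    # BIOM stores observations (features) as rows; pipeline wants samples x features
    return pd.DataFrame(mat.T, index=sample_ids, columns=obs_ids)


def _read_biom_hdf5(path: Path) -> pd.DataFrame:
    """Minimal reader for the BIOM 2.1 HDF5 dialect (CSR under observation/)."""
    import h5py
    from scipy import sparse

    with h5py.File(path, "r") as fh:
        obs_ids = [x.decode() if isinstance(x, bytes) else x for x in fh["observation/ids"][:]]
        sample_ids = [x.decode() if isinstance(x, bytes) else x for x in fh["sample/ids"][:]]
        grp = fh["observation/matrix"]
        mat = sparse.csr_matrix(
            (grp["data"][:], grp["indices"][:], grp["indptr"][:]),
            shape=(len(obs_ids), len(sample_ids)),
        )
    return pd.DataFrame(mat.toarray().T, index=sample_ids, columns=obs_ids)


def _parse_taxonomy(raw: pd.DataFrame) -> pd.DataFrame:
    """Normalise a taxonomy table to the six canonical rank columns.

    Accepts either one ';'-separated lineage-string column (QIIME2 style,
    7 ranks with a leading Domain/Kingdom) or one column per rank.
    """
    rank_cols = [c for c in raw.columns if c.strip().title() in LEVELS]
    if rank_cols:
        tax = pd.DataFrame(index=raw.index)
        for col in rank_cols:
            tax[col.strip().title()] = raw[col].map(_strip_rank_prefix)
        return tax[[lv for lv in LEVELS if lv in tax.columns]]
    if raw.shape[1] >= 1:
        lineage_col = raw.columns[0]
        split = raw[lineage_col].astype(str).str.split(";")
        prefix_to_level = {v: k for k, v in LEVEL_PREFIXES.items()}

        def ranks_of(parts):
            parts = [s.strip() for s in parts]
            out = {lv: None for lv in LEVELS}
            prefixed = [p for p in parts if len(p) > 2 and p[1:3] == "__"]
            if prefixed:
                # QIIME2/SILVA style: map each token by its rank prefix
                for p in parts:
                    if len(p) > 2 and p[1:3] == "__" and p[0] in prefix_to_level:
                        out[prefix_to_level[p[0]]] = _strip_rank_prefix(p)
            else:
                # bare ranks: positional, dropping a leading domain if 7 given
                if len(parts) == 7:
                    parts = parts[1:]
                for lv, p in zip(LEVELS, parts):
                    out[lv] = _strip_rank_prefix(p)
            return [out[lv] for lv in LEVELS]

        mat = pd.DataFrame(
            [ranks_of(p) for p in split], index=raw.index, columns=list(LEVELS)
        )
        return mat
    raise ValueError("taxonomy table has no usable rank columns")


def read_profile(counts_source, taxonomy_source, metadata_source) -> TaxonomicProfile:
    """Read and validate the (counts, taxonomy, metadata) table trio.

    Counts may be TSV (features as rows or columns, auto-detected by ID
    overlap with the taxonomy table) or BIOM (JSON or HDF5 dialect).
    SILVA-style rank prefixes (``g__``) are stripped into clean names.
    """
    counts_path = Path(counts_source)
    try:
        tax_raw = _read_table(taxonomy_source)
        taxonomy = _parse_taxonomy(tax_raw)
        if taxonomy.shape[1] < 1:
            raise ValueError("no rank columns")
    except Exception as exc:
        raise ValueError(f"cannot parse taxonomy file {taxonomy_source}: {exc}") from exc
    if counts_path.suffix == ".biom":
        try:
            counts = _read_biom_hdf5(counts_path)
        except OSError:
            counts = _read_biom_json(counts_path)
    else:
        counts = _read_table(counts_path)
        # orient to samples x features by matching IDs against the taxonomy
        row_hits = counts.index.isin(taxonomy.index).sum()
        col_hits = counts.columns.isin(taxonomy.index).sum()
        if row_hits > col_hits:
            counts = counts.T
    counts = counts.astype(float)
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("counts matrix contains non-integer values")
    counts = counts.round().astype(np.int64)
    metadata = _read_table(metadata_source)
    return TaxonomicProfile(counts=counts, taxonomy=taxonomy, metadata=metadata)


def filter_samples_by_depth(profile: TaxonomicProfile, min_reads: int = 1000) -> TaxonomicProfile:
    """Drop samples with library size below ``min_reads`` (default 1000).

    Shallow libraries are unreliable in both diversity and sequencing
    quality; the boundary is inclusive (exactly ``min_reads`` is kept).
    """
    if min_reads <= 0:
        raise ValueError("min_reads must be positive")
    depths = profile.library_sizes()
    keep = depths >= min_reads
    removed = depths.index[~keep].tolist()
    if removed:
        logger.info("depth filter removed %d samples: %s", len(removed), removed)
    if not keep.any():
        raise ValueError(f"all samples have library size < {min_reads}")
    return TaxonomicProfile(
        counts=profile.counts.loc[keep],
        taxonomy=profile.taxonomy,
        metadata=profile.metadata.loc[keep],
    )


def subset_condition(profile: TaxonomicProfile, column: str, value: str) -> TaxonomicProfile:
    """Restrict the profile to samples with ``metadata[column] == value``.

    All-zero features are kept; rare-taxon removal happens later at the
    prevalence filter, where it is condition-specific.
    """
    if column not in profile.metadata.columns:
        raise KeyError(f"metadata has no column {column!r}")
    keep = profile.metadata[column].astype(str) == str(value)
    if not keep.any():
        raise ValueError(f"no samples with {column} == {value!r}")
    return TaxonomicProfile(
        counts=profile.counts.loc[keep],
        taxonomy=profile.taxonomy,
        metadata=profile.metadata.loc[keep],
    )


def build_stacked_matrix(
    profile: TaxonomicProfile,
    levels=LEVELS,
    prevalence_threshold: float = 0.10,
    condition_label: str = "",
    min_library_size: int | None = None,
) -> StackedTaxaMatrix:
    """Aggregate features per rank, stack the rank tables, prevalence-filter.

    At each rank, feature counts are summed per distinct assignment name;
    features unassigned at a rank are simply excluded from that rank's
    aggregation (they still contribute where they are assigned).  The
    per-rank tables are concatenated column-wise in canonical rank order
    (names lexicographic within a rank), then taxa present (count > 0) in
    fewer than ``prevalence_threshold`` of the samples are removed; the
    boundary is inclusive (exactly the threshold fraction is kept).
    """
    if profile.counts.shape[0] < 2:
        raise ValueError("need at least 2 samples to build a stacked matrix")
    if not 0 <= prevalence_threshold <= 1:
        raise ValueError("prevalence_threshold must be a fraction in [0, 1]")
    unknown = [lv for lv in levels if lv not in LEVELS]
    if unknown:
        raise ValueError(f"unknown levels: {unknown}")
    blocks = []
    records = []
    tax = profile.taxonomy.loc[profile.counts.columns]
    for level in [lv for lv in LEVELS if lv in levels]:
        if level not in tax.columns:
            continue
        names = tax[level].map(_strip_rank_prefix)
        assigned = names.notna()
        if not assigned.any():
            continue
        sub = profile.counts.loc[:, assigned.values]
        grouped = sub.T.groupby(names[assigned].values).sum().T
        grouped = grouped[sorted(grouped.columns)]
        prefix = LEVEL_PREFIXES[level]
        lineages = _level_lineages(tax, level)
        for name in grouped.columns:
            records.append(
                {
                    "taxon_id": f"{prefix}__{name}",
                    "level": level,
                    "name": name,
                    "lineage": lineages.get(name, name),
                }
            )
        grouped.columns = [f"{prefix}__{n}" for n in grouped.columns]
        blocks.append(grouped)
    if not blocks:
        raise ValueError("no taxa could be aggregated at any requested level")
    stacked = pd.concat(blocks, axis=1)
    taxa = pd.DataFrame(records)
    prevalence = (stacked > 0).mean(axis=0)
    keep = prevalence >= prevalence_threshold
    if not keep.any():
        raise ValueError(
            f"no taxa pass the {prevalence_threshold:.0%} prevalence filter"
        )
    stacked = stacked.loc[:, keep.values]
    taxa = taxa[keep.values].reset_index(drop=True)
    provenance = {
        "min_library_size": min_library_size,
        "prevalence_threshold": prevalence_threshold,
        "prevalence_applied": "after stacking (criterion is per-column, so per-level "
        "before stacking would be equivalent)",
        "levels": [lv for lv in LEVELS if lv in levels],
        "n_samples": int(stacked.shape[0]),
    }
    return StackedTaxaMatrix(
        counts=stacked,
        taxa=taxa,
        condition_label=condition_label,
        provenance=provenance,
    )


def _level_lineages(tax: pd.DataFrame, level: str) -> dict:
    """Map each assignment name at ``level`` to one full lineage string."""
    upto = [lv for lv in LEVELS if lv in tax.columns][: LEVELS.index(level) + 1]
    upto = [lv for lv in upto if lv in tax.columns]
    out: dict = {}
    names = tax[level].map(_strip_rank_prefix)
    for fid, name in names.items():
        if name is None or name in out:
            continue
        parts = []
        for lv in upto:
            val = _strip_rank_prefix(tax.at[fid, lv])
            if val is not None:
                parts.append(f"{LEVEL_PREFIXES[lv]}__{val}")
        out[name] = ";".join(parts)
    return out
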
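"""End-to-end orchestration: single-condition runs and two-condition comparison.

A *bundle* is a directory holding one condition's artifacts: the stacked
matrix, correlation matrices (r/p/q TSV + long-format edges), the pattern
sweep, consensus matrix, module membership, plots, and a provenance
sidecar (config hash, seed, package version) so that equal hashes imply
equal numeric content.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .consensus_modules import find_modules
from .influence import classify_edges, influential_taxa, intra_modular_edges
from .io_profiles import (
    StackedTaxaMatrix,
    build_stacked_matrix,
    filter_samples_by_depth,
    read_profile,
    subset_condition,
)
from .network_tom import build_tom
from .preservation import module_preservation, shared_taxa_report
from .sparcc import CorrelationEstimate, estimate_correlations
from . import report as rpt

__all__ = ["run_single_condition", "compare_conditions", "load_bundle"]

logger = logging.getLogger(__name__)


def _write_provenance(outdir: Path, config: RunConfig, stage: str) -> None:
    sidecar = {
        "stage": stage,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
    }
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(sidecar, fh, indent=2, default=str)


def _write_square(outdir: Path, name: str, mat: np.ndarray, taxa) -> None:
    pd.DataFrame(mat, index=taxa, columns=taxa).to_csv(outdir / name, sep="\t")


def run_single_condition(
    config: RunConfig,
    counts_source,
    taxonomy_source,
    metadata_source,
    outdir,
    condition_column: str | None = None,
    condition_value: str | None = None,
    min_modules: int | None = None,
) -> dict:
    """io -> SparCC -> TOM -> consensus modules, all artifacts on disk.

    Returns a dict with the in-memory stage outputs for programmatic use.
    """
    if config.seed is None:
        raise ValueError("config.seed must be set for a reproducible run")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    profile = read_profile(counts_source, taxonomy_source, metadata_source)
    if condition_column is not None:
        profile = subset_condition(profile, condition_column, condition_value)
    profile = filter_samples_by_depth(profile, config.min_reads)
    stacked = build_stacked_matrix(
        profile,
        prevalence_threshold=config.prevalence_threshold,
        condition_label=condition_value or "",
        min_library_size=config.min_reads,
    )
    stacked.write(outdir / "stacked_counts.tsv", outdir / "stacked_taxa.tsv")

    corr = estimate_correlations(
        stacked.counts.to_numpy(),
        B=config.n_bootstraps,
        seed=config.seed,
        taxa=stacked.taxon_ids,
        exclusion_threshold=config.exclusion_threshold,
        max_exclusion_rounds=config.max_exclusion_rounds,
        inner_iterations=config.inner_iterations,
    )
    _write_square(outdir, "r.tsv", corr.r, stacked.taxon_ids)
    _write_square(outdir, "p.tsv", corr.p, stacked.taxon_ids)
    _write_square(outdir, "q.tsv", corr.q, stacked.taxon_ids)
    corr.edge_table().to_csv(outdir / "edges_all.tsv", sep="\t", index=False)

    tom = build_tom(corr.r, beta=config.beta, clip_negative_r=config.clip_negative_r)
    _write_square(outdir, "tom.tsv", tom.tom, stacked.taxon_ids)

    sweep, cons, solution = find_modules(
        tom.dissim,
        min_sizes=config.min_sizes,
        min_modules=min_modules if min_modules is not None else config.min_modules,
        zero_prop_max=config.zero_prop_max,
        height_fraction=config.height_fraction,
    )
    pattern_df = pd.DataFrame(
        {f"min_size_{m}": sweep.labels[m] for m in sweep.min_sizes},
        index=stacked.taxon_ids,
    )
    pattern_df.to_csv(outdir / "pattern_sweep.tsv", sep="\t")
    _write_square(outdir, "consensus.tsv", cons.C, stacked.taxon_ids)
    membership = stacked.taxa.copy()
    membership["module"] = solution.labels
    membership.to_csv(outdir / "membership.tsv", sep="\t", index=False)
    rpt.plot_pattern_grid(sweep, outdir / "pattern_grid.png")
    rpt.plot_silhouette_curve(solution, outdir / "silhouette.png")
    rpt.plot_consensus_heatmap(cons, outdir / "consensus.png", labels=solution.labels)
    _write_provenance(outdir, config, stage="single_condition")
    return {
        "profile": profile,
        "stacked": stacked,
        "correlation": corr,
        "tom": tom,
        "sweep": sweep,
        "consensus": cons,
        "solution": solution,
    }


def load_bundle(bundle_dir) -> dict:
    """Re-load the artifacts of a run_single_condition bundle."""
    bundle_dir = Path(bundle_dir)
    for required in ("stacked_counts.tsv", "r.tsv", "q.tsv", "membership.tsv"):
        if not (bundle_dir / required).exists():
            raise FileNotFoundError(f"bundle file missing: {bundle_dir / required}")
    counts = pd.read_csv(bundle_dir / "stacked_counts.tsv", sep="\t", index_col=0)
    taxa = pd.read_csv(bundle_dir / "stacked_taxa.tsv", sep="\t")
    membership = pd.read_csv(bundle_dir / "membership.tsv", sep="\t")
    r = pd.read_csv(bundle_dir / "r.tsv", sep="\t", index_col=0)
    p = pd.read_csv(bundle_dir / "p.tsv", sep="\t", index_col=0)
    q = pd.read_csv(bundle_dir / "q.tsv", sep="\t", index_col=0)
    with open(bundle_dir / "provenance.json") as fh:
        provenance = json.load(fh)
    corr = CorrelationEstimate(
        r=r.to_numpy(),
        p=p.to_numpy(),
        q=np.maximum(q.to_numpy(), p.to_numpy()),
        n_bootstraps=provenance["config"]["n_bootstraps"],
        seed=provenance["config"]["seed"],
        basis_variances=np.full(r.shape[0], np.nan),
        taxa=list(r.columns),
    )
    stacked = StackedTaxaMatrix(
        counts=counts,
        taxa=taxa,
        condition_label=str(provenance.get("condition", "")),
        provenance=provenance["config"],
    )
    return {
        "stacked": stacked,
        "correlation": corr,
        "membership": membership,
        "labels": membership["module"].to_numpy(),
        "provenance": provenance,
    }


def compare_conditions(config: RunConfig, bundle_a, bundle_b, outdir) -> dict:
    """Preservation (both directions), edge classification, influence report."""
    if config.seed is None:
        raise ValueError("config.seed must be set for a reproducible comparison")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    a = load_bundle(bundle_a) if not isinstance(bundle_a, dict) else bundle_a
    b = load_bundle(bundle_b) if not isinstance(bundle_b, dict) else bundle_b
    taxa_a = a["correlation"].taxa
    taxa_b = b["correlation"].taxa
    if not set(taxa_a) & set(taxa_b):
        raise ValueError(
            "conditions share no taxon ids; check that both bundles were "
            "built with the same taxonomy naming"
        )

    shared = shared_taxa_report(a["stacked"], b["stacked"])
    shared.drop(columns=["shared_taxa", "ref_only_taxa", "test_only_taxa"]).to_csv(
        outdir / "shared_taxa.tsv", sep="\t", index=False
    )

    results = {"shared_taxa": shared}
    for name, ref, test in (("A_in_B", a, b), ("B_in_A", b, a)):
        stats = module_preservation(
            ref["correlation"].taxa,
            ref["labels"],
            ref["correlation"].r,
            test["correlation"].taxa,
            test["correlation"].r,
            beta=config.beta,
            n_permutations=config.n_permutations,
            seed=config.seed,
        )
        stats.table.to_csv(outdir / f"preservation_{name}.tsv", sep="\t")
        rpt.plot_preservation_scatter(
            stats.table, outdir / f"preservation_{name}.png", title=name
        )
        results[f"preservation_{name}"] = stats

    edges_a = intra_modular_edges(
        a["correlation"], a["labels"], config.r_min, config.q_max, condition="A"
    )
    edges_b = intra_modular_edges(
        b["correlation"], b["labels"], config.r_min, config.q_max, condition="B"
    )
    classification = classify_edges(
        edges_a.same_module_only(), edges_b.same_module_only()
    )
    classification.table.to_csv(outdir / "edges_classified.tsv", sep="\t", index=False)
    rpt.edges_to_graphml(classification, outdir / "edges_classified.graphml")

    influence = influential_taxa(
        edges_a,
        taxa_a,
        a["labels"],
        edges_b,
        taxa_b,
        b["labels"],
        q_threshold=config.q_max,
    )
    influence.table.to_csv(outdir / "influence.tsv", sep="\t", index=False)
    for taxon in influence.table.loc[influence.table["influential"], "taxon"].head(20):
        safe = taxon.replace("/", "_")
        try:
            rpt.plot_log2_abundance(
                a["stacked"], b["stacked"], taxon, outdir / f"abundance_{safe}.png"
            )
        except KeyError:
            pass
    results.update(
        {
            "edges_A": edges_a,
            "edges_B": edges_b,
            "classification": classification,
            "influence": influence,
        }
    )
    _write_provenance(outdir, config, stage="compare_conditions")
    return results
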
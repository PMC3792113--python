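"""End-to-end orchestration: manifest -> per-study statistics -> gate ->
meta-analysis/aggregation -> summary matrices -> run report.

All numerical work happens at full precision; rounding for display is
confined to the writers. Two runs on identical inputs and configuration
produce byte-identical output tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .diffexp import analyze_study, attach_study_metadata
from .gate import DEFAULT_CRITERIA, ThresholdCriteria, filter_above_threshold
from .meta_summary import aggregate_folds_all, build_summary_matrix, meta_analyze_all
from .study_io import (
    StudyManifest,
    load_studies,
    read_manifest,
    write_records_table,
    write_results_table,
    write_table,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    manifest: Path
    out_dir: Path
    criteria: ThresholdCriteria = field(default_factory=ThresholdCriteria)
    min_datasets: int = 5
    gene_whitelist: Sequence[str] | None = None
    monotone_q: bool = False
    log_transform: bool = True
    welch: bool = False
    make_plots: bool = False


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the whole screen and write every stage's table under out_dir.

    Outputs: ``results.tsv`` (per-study per-gene statistics),
    ``records.tsv`` (above-threshold analyses), ``meta_summary.tsv``,
    ``fold_aggregates.tsv``, ``summary_over.tsv``/``summary_under.tsv``
    (best-percentile matrices) and ``run_report.json``. Returns the run
    report as a dict. An empty gated set is reported, not an error.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = read_manifest(config.manifest)
    studies = load_studies(manifest)
    logger.info("loaded %d studies", len(studies))

    per_study = [
        analyze_study(
            s,
            log_transform=config.log_transform,
            welch=config.welch,
            monotone_q=config.monotone_q,
        )
        for s in studies
    ]
    results = pd.concat(per_study, ignore_index=True)
    results = attach_study_metadata(results, studies)
    results = results.sort_values(["study_id", "gene"], kind="stable").reset_index(drop=True)
    write_results_table(results, out / "results.tsv")

    records = filter_above_threshold(
        results, config.criteria, gene_whitelist=config.gene_whitelist
    )
    write_records_table(records, out / "records.tsv")
    logger.info("gated %d above-threshold analyses", len(records))

    scope = results
    if config.gene_whitelist is not None:
        scope = results[results["gene"].isin(set(config.gene_whitelist))]
    meta = meta_analyze_all(scope, min_datasets=config.min_datasets)
    write_table(meta, out / "meta_summary.tsv")

    folds = aggregate_folds_all(records)
    write_table(folds, out / "fold_aggregates.tsv")

    genes = (
        list(config.gene_whitelist)
        if config.gene_whitelist is not None
        else sorted(results["gene"].unique())
    )
    cancers = sorted(results["cancer_type"].unique())
    matrix = build_summary_matrix(records, genes, cancers)
    for direction, mat in (("over", matrix.over), ("under", matrix.under)):
        mat.index.name = "gene"
        mat.to_csv(out / f"summary_{direction}.tsv", sep="\t", na_rep="NA")
    if config.make_plots:
        from .plotting import plot_summary_matrix

        plot_summary_matrix(matrix, out / "summary_matrix.png")

    report = {
        "oncoscreen_version": __version__,
        "manifest": str(config.manifest),
        "thresholds": {
            "p_max": config.criteria.p_max,
            "fold_min": config.criteria.fold_min,
            "percentile_max": config.criteria.percentile_max,
        },
        "min_datasets": config.min_datasets,
        "monotone_q": config.monotone_q,
        "log_transform": config.log_transform,
        "welch": config.welch,
        "gene_whitelist": (
            sorted(config.gene_whitelist) if config.gene_whitelist is not None else None
        ),
        "counts": {
            "studies": len(studies),
            "genes_tested": int(results[["study_id", "gene"]].drop_duplicates().shape[0]),
            "above_threshold_records": int(len(records)),
            "meta_summaries": int(len(meta)),
            "fold_aggregates": int(len(folds)),
        },
    }
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
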
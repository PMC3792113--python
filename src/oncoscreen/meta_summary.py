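"""Cross-study aggregation: median-rank meta-analysis, fold-change
summaries and the over/under gene-summary matrices.

The comparative meta-analysis summarises a gene's behaviour in a cancer
subtype by the median p-value and median gene rank across *all* n datasets
in which the gene was measured — not only the above-threshold ones — and
is performed only when n >= ``min_datasets`` (default 5). A subtype trend
is called significant when the median p-value is at or below 0.05.

Fold-change aggregation reports mean +/- SEM of the absolute linear fold
change over the above-threshold analyses of one gene/subtype/direction;
direction is carried separately, so a "mean fold decrease of 2.96" keeps
its magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .study_io import FOLD_COLUMNS, META_COLUMNS, StudyValidationError

SIGNIFICANCE_LEVEL = 0.05
PERCENTILE_BINS = (1, 5, 10)


@dataclass(frozen=True)
class MetaSummary:
    """Median-based cross-study summary for one (gene, cancer subtype)."""

    gene: str
    cancer_subtype: str
    n_datasets: int
    median_p: float
    median_rank: float
    significant: bool


@dataclass(frozen=True)
class FoldAggregate:
    """Mean +/- SEM of |fold change| over above-threshold analyses.

    ``sem_fold`` is None when only one analysis exists (a sample SD needs
    k >= 2)."""

    gene: str
    cancer_subtype: str
    direction: str
    k: int
    mean_fold: float
    sem_fold: float | None


@dataclass
class GeneSummaryMatrix:
    """Per-direction gene x cancer-type matrices of best percentiles.

    ``over``/``under`` hold the lowest (best) percentile among
    above-threshold analyses of that direction, NaN where none exist;
    ``over_binned``/``under_binned`` map cells onto the display classes
    "1%", "5%", "10%" (empty string = no above-threshold analysis)."""

    over: pd.DataFrame
    under: pd.DataFrame
    over_binned: pd.DataFrame
    under_binned: pd.DataFrame


def meta_analyze(
    gene: str,
    subtype: str,
    all_results: pd.DataFrame,
    min_datasets: int = 5,
) -> MetaSummary | None:
    """Median p / median rank meta-analysis for one gene in one subtype.

    ``all_results`` is the concatenated per-study results frame with
    ``cancer_subtype`` attached, spanning every dataset that measured the
    gene (above threshold or not). Returns None (the not-eligible marker)
    when fewer than ``min_datasets`` datasets measured the gene.
    """
    sub = all_results[
        (all_results["gene"] == gene) & (all_results["cancer_subtype"] == subtype)
    ]
    if len(sub) == 0:
        raise StudyValidationError(f"{gene}: unmeasured in every study of {subtype!r}")
    n = int(sub["study_id"].nunique())
    if n < min_datasets:
        return None
    median_p = float(sub["p"].median())
    median_rank = float(sub["rank"].median())
    return MetaSummary(
        gene=gene,
        cancer_subtype=subtype,
        n_datasets=n,
        median_p=median_p,
        median_rank=median_rank,
        significant=median_p <= SIGNIFICANCE_LEVEL,
    )


def meta_analyze_all(all_results: pd.DataFrame, min_datasets: int = 5) -> pd.DataFrame:
    """Meta-analysis over every (gene, subtype) with enough datasets."""
    grouped = all_results.groupby(["gene", "cancer_subtype"], sort=True)
    rows = []
    for (gene, subtype), sub in grouped:
        n = int(sub["study_id"].nunique())
        if n < min_datasets:
            continue
        mp = float(sub["p"].median())
        rows.append((gene, subtype, n, mp, float(sub["rank"].median()),
                     mp <= SIGNIFICANCE_LEVEL))
    return pd.DataFrame(rows, columns=META_COLUMNS)


def aggregate_folds(records: pd.DataFrame) -> FoldAggregate:
    """Aggregate |fold change| over the records of ONE gene/subtype/direction."""
    if len(records) == 0:
        raise StudyValidationError("aggregate_folds: no records")
    for col in ("gene", "cancer_subtype", "direction"):
        if records[col].nunique() != 1:
            raise StudyValidationError(
                f"aggregate_folds: records mix multiple values of {col!r}"
            )
    folds = records["fold_change"].abs().to_numpy(float)
    k = len(folds)
    mean = float(np.mean(folds))
    sem = float(np.std(folds, ddof=1) / np.sqrt(k)) if k > 1 else None
    return FoldAggregate(
        gene=str(records["gene"].iloc[0]),
        cancer_subtype=str(records["cancer_subtype"].iloc[0]),
        direction=str(records["direction"].iloc[0]),
        k=k,
        mean_fold=mean,
        sem_fold=sem,
    )


def aggregate_folds_all(records: pd.DataFrame) -> pd.DataFrame:
    """Fold aggregation for every gene/subtype/direction present in records."""
    rows = []
    for _, sub in records.groupby(["gene", "cancer_subtype", "direction"], sort=True):
        agg = aggregate_folds(sub)
        rows.append((agg.gene, agg.cancer_subtype, agg.direction, agg.k,
                     agg.mean_fold, np.nan if agg.sem_fold is None else agg.sem_fold))
    return pd.DataFrame(rows, columns=FOLD_COLUMNS)


def count_above_threshold(
    records: pd.DataFrame,
    gene: str | None = None,
    subtype: str | None = None,
    direction: str | None = None,
) -> int:
    """Exact count of records matching the given filters (None = any)."""
    mask = pd.Series(True, index=records.index)
    if gene is not None:
        mask &= records["gene"] == gene
    if subtype is not None:
        mask &= records["cancer_subtype"] == subtype
    if direction is not None:
        mask &= records["direction"] == direction
    return int(mask.sum())


def bin_percentile(percentile: float) -> str:
    """Map a best percentile onto the three display classes 1%/5%/10%."""
    if np.isnan(percentile):
        return ""
    for edge in PERCENTILE_BINS:
        if percentile <= edge:
            return f"{edge}%"
    return f">{PERCENTILE_BINS[-1]}%"


def build_summary_matrix(
    records: pd.DataFrame,
    genes: Sequence[str],
    cancers: Sequence[str],
) -> GeneSummaryMatrix:
    """Build the over/under summary matrices over a fixed gene and
    cancer-type layout.

    Each cell holds the best (lowest) percentile among the above-threshold
    analyses of that gene/cancer-type/direction, or NaN when none exist; a
    gene that never passed the gate therefore has entirely empty rows in
    both matrices.
    """
    mats = {}
    for direction in ("over", "under"):
        mat = pd.DataFrame(np.nan, index=list(genes), columns=list(cancers))
        sub = records[records["direction"] == direction]
        best = sub.groupby(["gene", "cancer_type"])["percentile"].min()
        for (gene, cancer), pct in best.items():
            if gene in mat.index and cancer in mat.columns:
                mat.loc[gene, cancer] = pct
        mats[direction] = mat
    return GeneSummaryMatrix(
        over=mats["over"],
        under=mats["under"],
        over_binned=mats["over"].map(bin_percentile),
        under_binned=mats["under"].map(bin_percentile),
    )
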
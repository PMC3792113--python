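"""Boolean-AND threshold gate producing above-threshold analysis records.

An analysis (one gene in one study) is "above threshold" only when it
clears all three criteria simultaneously: p-value below the cut-off, at
least the minimum absolute linear fold change, and a gene-rank percentile
within the top slice of the study's ranking.

Boundary conventions: p strictly below ``p_max``; fold change inclusive
(|fc| >= ``fold_min``, so a printed 2.05 or -2.071 at the default 2.0
passes); percentile inclusive (<= ``percentile_max`` after the ceiling,
so integer percentile 10 passes the default top-10% gate).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .study_io import RECORD_COLUMNS, StudyValidationError, sort_records


@dataclass(frozen=True)
class ThresholdCriteria:
    """Gate constants combined by Boolean AND."""

    p_max: float = 0.05
    fold_min: float = 2.0
    percentile_max: int = 10

    def __post_init__(self) -> None:
        if not (0.0 < self.p_max < 1.0):
            raise StudyValidationError("p_max must lie in (0, 1)")
        if self.fold_min < 1.0:
            raise StudyValidationError("fold_min must be >= 1")
        if not (1 <= self.percentile_max <= 100):
            raise StudyValidationError("percentile_max must lie in 1..100")


DEFAULT_CRITERIA = ThresholdCriteria()


def _get(result, *names):
    for name in names:
        if isinstance(result, Mapping) or isinstance(result, pd.Series):
            if name in result:
                return result[name]
        elif hasattr(result, name):
            return getattr(result, name)
    raise KeyError(f"result lacks fields {names}")


def passes_threshold(result, criteria: ThresholdCriteria = DEFAULT_CRITERIA) -> bool:
    """True iff p < p_max AND |fold_change| >= fold_min AND
    percentile <= percentile_max. Accepts a GeneResult, mapping or Series
    (``p`` or ``p_value`` both recognised). An undefined (NaN) fold change
    never passes."""
    p = float(_get(result, "p", "p_value"))
    fc = float(_get(result, "fold_change"))
    pct = int(_get(result, "percentile"))
    if np.isnan(fc):
        return False
    return (p < criteria.p_max) and (abs(fc) >= criteria.fold_min) and (
        pct <= criteria.percentile_max
    )


def filter_above_threshold(
    results: pd.DataFrame,
    criteria: ThresholdCriteria = DEFAULT_CRITERIA,
    gene_whitelist: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Extract the above-threshold (gene, study) analyses as a records table.

    ``results`` is a per-study results frame (possibly concatenated over
    studies) that already carries ``cancer_type`` and ``cancer_subtype``
    columns; see :func:`oncoscreen.diffexp.attach_study_metadata`. When a
    whitelist is given (e.g. the 15 KCNK family genes) only those genes are
    considered. Output rows are in the deterministic records order.
    """
    needed = {"gene", "cancer_type", "cancer_subtype", "direction",
              "fold_change", "percentile", "study_id"}
    missing = needed - set(results.columns)
    if missing:
        raise StudyValidationError(f"results frame missing columns {sorted(missing)}")
    p_col = "p" if "p" in results.columns else "p_value"

    df = results
    if gene_whitelist is not None:
        df = df[df["gene"].isin(set(gene_whitelist))]
    fc = df["fold_change"].astype(float)
    mask = (
        (df[p_col].astype(float) < criteria.p_max)
        & fc.notna()
        & (fc.abs() >= criteria.fold_min)
        & (df["percentile"].astype(int) <= criteria.percentile_max)
    )
    hits = df.loc[mask]
    records = pd.DataFrame(
        {
            "gene": hits["gene"],
            "cancer_type": hits["cancer_type"],
            "cancer_subtype": hits["cancer_subtype"],
            "direction": hits["direction"],
            "p_value": hits[p_col].astype(float),
            "fold_change": fc.loc[mask],
            "percentile": hits["percentile"].astype(int),
            "study_id": hits["study_id"],
        }
    )
    return sort_records(records[RECORD_COLUMNS]) if len(records) else records[RECORD_COLUMNS]
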
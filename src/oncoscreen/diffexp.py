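"""Per-study differential-expression statistics.

For every gene measured in a study the screen computes, cancer vs normal:

* a two-sided two-sample Student's t-test (pooled variance by default,
  Welch behind a flag), applied to log2-transformed intensities;
* the signed linear fold change, mean(cancer)/mean(normal) with ratios
  below 1 reported as the negative reciprocal (ratio 1/9.574 -> -9.574);
* the gene rank R: position of the gene's p-value among all N measured
  genes of the study, smallest p first, ties broken by gene id;
* the gene-rank percentile ceil(100*R/N), printed as an integer 1..100;
* the rank-based false-discovery-rate estimate Q = N*P/R, optionally made
  monotone by the step-up running minimum.

Testing on the log2 scale while reporting fold change on the linear scale
is the classical microarray convention: log intensities are closer to
normal with stable variance, while "2-fold" is a linear statement.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from dataclasses import dataclass
from scipy import stats

from .study_io import CANCER, NORMAL, RESULT_COLUMNS, ExpressionStudy, StudyValidationError

OVER = "over"
UNDER = "under"

_TINY = np.finfo(float).tiny  # lower clamp keeping p, q in (0, 1]


@dataclass(frozen=True)
class GeneResult:
    """Differential-expression statistics for one gene in one study."""

    gene: str
    study_id: str
    t: float
    p: float
    fold_change: float
    direction: str
    rank: int
    n_genes: int
    percentile: int
    q: float


def gene_t_test(
    cancer_values,
    normal_values,
    *,
    log_transform: bool = True,
    welch: bool = False,
) -> tuple[float, float]:
    """Two-sided two-sample t-test for one gene.

    Inputs are linear intensities; the test itself runs on log2 values
    unless ``log_transform=False``. Missing values are dropped first.
    Two identical constant groups are a defined no-difference outcome
    (t=0, p=1), not an error.
    """
    c = np.asarray(cancer_values, dtype=float)
    n = np.asarray(normal_values, dtype=float)
    c, n = c[np.isfinite(c)], n[np.isfinite(n)]
    if c.size < 2 or n.size < 2:
        raise StudyValidationError("t-test needs >=2 finite values per group")
    if log_transform:
        if (c <= 0).any() or (n <= 0).any():
            raise StudyValidationError("log2 transform requires positive intensities")
        c, n = np.log2(c), np.log2(n)
    t, p = _ttest_rows(c[None, :], n[None, :], welch=welch)
    return float(t[0]), float(p[0])


def _ttest_rows(c: np.ndarray, n: np.ndarray, *, welch: bool = False):
    """Row-wise two-sided t-test with NaN-aware degenerate-case handling."""
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # constant rows trigger scipy's catastrophic-cancellation warning;
        # those rows are resolved explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(c, n, axis=1, equal_var=not welch, nan_policy="omit")
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    # zero within-group variance in both groups: scipy yields NaN
    mc, mn = np.nanmean(c, axis=1), np.nanmean(n, axis=1)
    degen = ~np.isfinite(t)
    same = degen & np.isclose(mc, mn)
    diff = degen & ~np.isclose(mc, mn)
    t[same], p[same] = 0.0, 1.0
    t[diff] = np.where(mc[diff] > mn[diff], np.inf, -np.inf)
    p[diff] = _TINY
    p = np.clip(p, _TINY, 1.0)
    return t, p


def fold_change(cancer_values, normal_values) -> float:
    """Signed linear fold change from group means.

    Returns r = mean(cancer)/mean(normal) when r >= 1, else -1/r, so the
    magnitude is always >= 1 and the sign encodes the direction. Requires
    strictly positive group means (linear intensities); otherwise the fold
    change is undefined and NaN is returned.
    """
    c = np.asarray(cancer_values, dtype=float)
    n = np.asarray(normal_values, dtype=float)
    mc = np.nanmean(c) if np.isfinite(c).any() else np.nan
    mn = np.nanmean(n) if np.isfinite(n).any() else np.nan
    return float(_signed_ratio(np.asarray([mc]), np.asarray([mn]))[0])


def _signed_ratio(mc: np.ndarray, mn: np.ndarray) -> np.ndarray:
    out = np.full(mc.shape, np.nan)
    ok = np.isfinite(mc) & np.isfinite(mn) & (mc > 0) & (mn > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = mc / mn
        out[ok] = np.where(r[ok] >= 1.0, r[ok], -1.0 / r[ok])
    return out


def rank_and_percentile(p_values: pd.Series) -> pd.DataFrame:
    """Rank genes by p-value and attach the integer gene-rank percentile.

    ``p_values`` is indexed by gene id, one two-sided p per measured gene.
    R=1 is the smallest p; ties are broken by gene id so ranking is
    deterministic. The percentile is ceil(100*R/N) against the N genes
    measured in this study.
    """
    if len(p_values) == 0:
        raise StudyValidationError("rank_and_percentile: empty p-value vector")
    n = len(p_values)
    order = p_values.reset_index()
    order.columns = ["gene", "p"]
    order = order.sort_values(["p", "gene"], kind="stable")
    rank = pd.Series(np.arange(1, n + 1), index=order["gene"])
    rank = rank.loc[p_values.index]
    percentile = np.ceil(100.0 * rank.to_numpy() / n).astype(int)
    return pd.DataFrame({"rank": rank.to_numpy(), "percentile": percentile},
                        index=p_values.index)


def fdr_q(p_value, n_genes, rank, *, monotone: bool = False):
    """Rank-based FDR estimate Q = N*P/R.

    Scalar or vector. In ``monotone`` mode the step-up running minimum is
    applied (from the largest rank downward) and Q is capped at 1; raw mode
    is the default and reproduces the plain formula, so Q may exceed 1.
    """
    p = np.atleast_1d(np.asarray(p_value, dtype=float))
    r = np.atleast_1d(np.asarray(rank, dtype=int))
    if np.any((r < 1) | (r > n_genes)):
        raise StudyValidationError("fdr_q: rank out of range 1..n_genes")
    q = n_genes * p / r
    if monotone:
        order = np.argsort(r)
        q_sorted = np.minimum(1.0, q[order])
        q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
        q = np.empty_like(q_sorted)
        q[order] = q_sorted
    if np.isscalar(p_value) or np.ndim(p_value) == 0:
        return float(q[0])
    return q


def analyze_study(
    study: ExpressionStudy,
    *,
    log_transform: bool = True,
    welch: bool = False,
    monotone_q: bool = False,
) -> pd.DataFrame:
    """Full per-gene screen for one study.

    Genes left with fewer than two finite values in either group after
    missing-value removal are treated as not measured in this study: they
    are excluded from the output and from N. Output rows are sorted by
    gene id, so the result is invariant to input row order.

    Returns a DataFrame with columns ``study_id, gene, t, p, fold_change,
    direction, rank, n_genes, percentile, q``.
    """
    values = study.values.sort_index()
    c = values[study.group_samples(CANCER)].to_numpy(float)
    n = values[study.group_samples(NORMAL)].to_numpy(float)

    measured = (np.isfinite(c).sum(axis=1) >= 2) & (np.isfinite(n).sum(axis=1) >= 2)
    genes = values.index[measured]
    if len(genes) == 0:
        raise StudyValidationError(f"{study.study_id}: no measurable genes")
    c, n = c[measured], n[measured]

    if log_transform:
        with np.errstate(invalid="ignore", divide="ignore"):
            lc = np.where(c > 0, np.log2(np.where(c > 0, c, 1.0)), np.nan)
            ln = np.where(n > 0, np.log2(np.where(n > 0, n, 1.0)), np.nan)
    else:
        lc, ln = c, n
    t, p = _ttest_rows(lc, ln, welch=welch)

    with np.errstate(invalid="ignore"):
        fc = _signed_ratio(np.nanmean(c, axis=1), np.nanmean(n, axis=1))
    direction = np.where(np.isnan(fc), "NA", np.where(fc > 0, OVER, UNDER))

    p_series = pd.Series(p, index=genes)
    rp = rank_and_percentile(p_series)
    n_genes = len(genes)
    q = fdr_q(p, n_genes, rp["rank"].to_numpy(), monotone=monotone_q)

    return pd.DataFrame(
        {
            "study_id": study.study_id,
            "gene": genes,
            "t": t,
            "p": p,
            "fold_change": fc,
            "direction": direction,
            "rank": rp["rank"].to_numpy(),
            "n_genes": n_genes,
            "percentile": rp["percentile"].to_numpy(),
            "q": q,
        }
    ).reset_index(drop=True)[RESULT_COLUMNS]


def attach_study_metadata(results: pd.DataFrame, studies) -> pd.DataFrame:
    """Join cancer_type / cancer_subtype onto per-study results by study_id."""
    meta = pd.DataFrame(
        [(s.study_id, s.cancer_type, s.cancer_subtype) for s in studies],
        columns=["study_id", "cancer_type", "cancer_subtype"],
    )
    return results.merge(meta, on="study_id", how="left")
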
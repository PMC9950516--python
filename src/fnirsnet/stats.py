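"""Group statistics: normality checks, two-sample t-tests with BH-FDR
correction, edgewise connectivity comparisons, 2x2 chi-square, and Pearson
correlations between network metrics and CRS-R scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .montage import ValidationError

__all__ = [
    "GroupComparison",
    "CorrelationResult",
    "normality_check",
    "two_sample_t",
    "t_from_summary",
    "bh_fdr",
    "edgewise_comparison",
    "chi_square_2x2",
    "crsr_correlation",
]


@dataclass
class GroupComparison:
    variable: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t: float
    df: float
    p_raw: float
    p_adj: float | None = None
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        p = self.p_adj if self.p_adj is not None else self.p_raw
        return bool(np.isfinite(p) and p < self.alpha)


@dataclass
class CorrelationResult:
    metric: str
    scale: str  # "total" or a CRS-R subscale name
    r: float
    p: float
    n: int


def normality_check(values: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk W statistic and p-value."""
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValidationError("Shapiro-Wilk needs n >= 3")
    if np.ptp(values) == 0:
        raise ValidationError("Shapiro-Wilk undefined for a constant vector")
    w, p = sps.shapiro(values)
    return float(w), float(p)


def two_sample_t(
    a: np.ndarray,
    b: np.ndarray,
    variant: str = "student",
    variable: str = "",
    alpha: float = 0.05,
) -> GroupComparison:
    """Two-sided two-sample t-test (pooled-variance Student by default;
    ``variant="welch"`` for unequal variances)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs n >= 2")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
        # identical constant groups: no difference by construction
        return GroupComparison(variable, a.mean(), 0.0, a.size, b.mean(), 0.0,
                               b.size, 0.0, a.size + b.size - 2, 1.0, alpha=alpha)
    equal_var = variant == "student"
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return GroupComparison(
        variable=variable,
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)), n_a=int(a.size),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)), n_b=int(b.size),
        t=float(res.statistic), df=float(res.df), p_raw=float(res.pvalue),
        alpha=alpha)


def t_from_summary(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
    variant: str = "student",
) -> tuple[float, float]:
    """Student (or Welch) t and two-sided p from summary statistics."""
    res = sps.ttest_ind_from_stats(mean_a, sd_a, n_a, mean_b, sd_b, n_b,
                                   equal_var=(variant == "student"))
    return float(res.statistic), float(res.pvalue)


def bh_fdr(
    pvalues: np.ndarray,
    q: float = 0.05,
    method: str = "fdr_bh",
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up (``method="fdr_by"`` for the dependent
    variant).  Returns (adjusted p-values, boolean rejection set)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("p-values must be a non-empty 1-D array")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method=method)
    return p_adj, reject


def edgewise_comparison(
    z_a: np.ndarray,
    z_b: np.ndarray,
    alpha: float = 0.01,
    fdr_method: str = "fdr_bh",
    variant: str = "student",
) -> pd.DataFrame:
    """Per-edge two-sample t over all node pairs with FDR across edges.

    ``z_a``/``z_b`` are stacked (subjects, n, n) rectified-z matrices of the
    two groups.  Returns a tidy frame with one row per upper-triangle edge
    (i < j node positions), t, raw and adjusted p, and the surviving flag;
    degenerate edges (zero variance in both groups) get NaN p and are
    excluded from the correction with a warning.
    """
    z_a = np.asarray(z_a, dtype=float)
    z_b = np.asarray(z_b, dtype=float)
    if z_a.ndim != 3 or z_b.ndim != 3 or z_a.shape[1:] != z_b.shape[1:]:
        raise ValidationError("expected stacked (subjects, n, n) matrices "
                              "with a common node set")
    if z_a.shape[0] < 2 or z_b.shape[0] < 2:
        raise ValidationError("each group needs >= 2 subjects")
    n = z_a.shape[1]
    iu, ju = np.triu_indices(n, k=1)
    flat_a = z_a[:, iu, ju]
    flat_b = z_b[:, iu, ju]
    degenerate = (flat_a.std(axis=0) == 0) & (flat_b.std(axis=0) == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = sps.ttest_ind(flat_a, flat_b, axis=0,
                            equal_var=(variant == "student"))
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    p[degenerate] = np.nan
    valid = np.isfinite(p)
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} degenerate edges excluded "
                      "from FDR", stacklevel=2)
    p_adj = np.full_like(p, np.nan)
    reject = np.zeros_like(p, dtype=bool)
    if valid.any():
        p_adj[valid], reject[valid] = bh_fdr(p[valid], q=alpha,
                                             method=fdr_method)
    return pd.DataFrame({
        "i": iu, "j": ju,
        "mean_a": flat_a.mean(axis=0), "mean_b": flat_b.mean(axis=0),
        "t": t, "p_raw": p, "p_adj": p_adj,
        "significant": reject,
        "direction": np.sign(flat_a.mean(axis=0) - flat_b.mean(axis=0)),
    })


def chi_square_2x2(counts: np.ndarray, correction: bool = False
                   ) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 count table (Yates correction optional)."""
    table = np.asarray(counts)
    if table.shape != (2, 2):
        raise ValidationError("expected a 2x2 table")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        table = table.astype(float)
        if np.any(table < 0) or np.any(table != np.round(table)):
            raise ValidationError("counts must be non-negative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValidationError("chi-square undefined with a zero marginal")
    res = sps.chi2_contingency(table, correction=correction)
    return float(res.statistic), float(res.pvalue)


def crsr_correlation(
    metric_values: np.ndarray,
    scores: np.ndarray,
    metric: str = "",
    scale: str = "total",
) -> CorrelationResult:
    """Pearson correlation between per-subject metric values and a CRS-R
    scale (total or one subscale), with two-sided p."""
    x = np.asarray(metric_values, dtype=float)
    y = np.asarray(scores, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("metric values and scores must be paired 1-D arrays")
    if x.size < 3:
        raise ValidationError("correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined for constant input")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(metric=metric, scale=scale, r=float(r),
                             p=float(p), n=int(x.size))
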
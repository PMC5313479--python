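"""Validation statistics for composite clinical scores.

Internal consistency (Cronbach's alpha), discriminant validity (two-group
t test with effect size r), concurrent validity (tie-corrected Spearman
rank correlations against external criteria) and Bonferroni control of
the family-wise error rate.

Conventions: alpha uses population-variance (denominator n) for both the
item variances and the total-score variance — only their ratio enters the
coefficient; the group comparison defaults to the Welch (unequal-variance)
t test, appropriate when group spreads differ grossly; missing data are
handled listwise within a scale for alpha and pairwise for correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class PsychometricsError(ValueError):
    pass


@dataclass
class ReliabilityResult:
    scale: str
    n_used: int
    alpha: float
    k_items: int


@dataclass
class GroupComparison:
    t_stat: float
    df: float
    p_value: float
    effect_r: float
    ci_low: float
    ci_high: float
    n_a: int
    n_b: int


@dataclass
class CorrelationResult:
    name: str
    method: str
    r: float
    p_value: float
    n_used: int
    significant: bool | None = None  # set after Bonferroni adjustment


def cronbach_alpha(items, scale: str = "") -> ReliabilityResult:
    """Cronbach's alpha: k/(k-1) * (1 - sum(item variances) / var(row sums)).

    ``items`` is an (n_subjects x k_items) array-like or DataFrame; rows
    with any missing item are excluded listwise and ``n_used`` reports the
    remainder.
    """
    mat = np.asarray(pd.DataFrame(items), dtype=float)
    if mat.ndim != 2 or mat.shape[1] < 2:
        raise PsychometricsError("alpha needs at least 2 items")
    mat = mat[~np.isnan(mat).any(axis=1)]
    n, k = mat.shape
    if n < 2:
        raise PsychometricsError(f"alpha needs >= 2 complete rows, got {n}")
    item_var = mat.var(axis=0, ddof=0)
    total_var = mat.sum(axis=1).var(ddof=0)
    if total_var == 0:
        raise PsychometricsError("total-score variance is zero; alpha undefined")
    alpha = k / (k - 1) * (1.0 - item_var.sum() / total_var)
    return ReliabilityResult(scale, n, float(alpha), k)


def discriminant_test(scores_a, scores_b, equal_var: bool = False) -> GroupComparison:
    """Two-sample comparison of total scores between known groups.

    Welch by default (``equal_var=False``); effect size
    r = sqrt(t^2 / (t^2 + df)); 95% CI of the mean difference a - b.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise PsychometricsError("each group needs n >= 2")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    ci = res.confidence_interval(0.95)
    t, df = float(res.statistic), float(res.df)
    effect_r = float(np.sqrt(t * t / (t * t + df)))
    return GroupComparison(
        t_stat=t,
        df=df,
        p_value=float(res.pvalue),
        effect_r=effect_r,
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        n_a=len(a),
        n_b=len(b),
    )


def rank_correlation(x, y, name: str = "", method: str = "spearman") -> CorrelationResult:
    """Tie-corrected Spearman (or Pearson) correlation with pairwise deletion."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise PsychometricsError("x and y must be paired")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise PsychometricsError(f"need n >= 3 non-missing pairs, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise PsychometricsError("correlation undefined for a constant vector")
    if method == "spearman":
        r, p = stats.spearmanr(x, y)
    elif method == "pearson":
        r, p = stats.pearsonr(x, y)
    else:
        raise PsychometricsError(f"unknown method {method!r}")
    return CorrelationResult(name, method, float(r), float(p), len(x))


def bonferroni(p_values, family_alpha: float = 0.05) -> np.ndarray:
    """Reject H0_i iff p_i <= family_alpha / m."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise PsychometricsError("empty p-value family")
    if np.any((p < 0) | (p > 1)):
        raise PsychometricsError("p-values must lie in [0, 1]")
    return p <= family_alpha / p.size


def concurrent_validity(
    cohort_scores: pd.DataFrame,
    criteria: pd.DataFrame,
    mcasco_total=None,
    family_alpha: float = 0.05,
) -> list[CorrelationResult]:
    """Correlate totals with each external criterion; Bonferroni-adjust.

    ``cohort_scores`` must carry a ``total`` column; ``criteria`` holds one
    column per criterion (e.g. ``clinician_rating``, ``ecog``), row-aligned.
    If ``mcasco_total`` is given, the short-form agreement (Pearson) joins
    the family.  Each result's ``significant`` flag is the Bonferroni
    decision at the family alpha.
    """
    total = np.asarray(cohort_scores["total"], dtype=float)
    results: list[CorrelationResult] = []
    for name in criteria.columns:
        results.append(
            rank_correlation(total, criteria[name], name=name, method="spearman")
        )
    if mcasco_total is not None:
        results.append(
            rank_correlation(
                total, mcasco_total, name="mcasco_agreement", method="pearson"
            )
        )
    if not results:
        raise PsychometricsError("no criterion columns present")
    decisions = bonferroni([r.p_value for r in results], family_alpha)
    for res, reject in zip(results, decisions):
        res.significant = bool(reject)
    return results
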
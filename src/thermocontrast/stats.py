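"""Inference chain: repeated-measures ANOVA, t-tests, BH correction, and
within-subject error bars, implemented directly from their sum-of-squares /
closed-form definitions (distribution functions from scipy.stats).

The one-way repeated-measures ANOVA uses the classical within-subject
decomposition

    SS_condition = n · Σ_j (m̄_j − m̄)²        df = k − 1
    SS_subject   = k · Σ_i (m̄_i − m̄)²        df = n − 1
    SS_error     = SS_total − SS_condition − SS_subject
    F            = MS_condition / MS_error     df = (k−1, (k−1)(n−1))

with no sphericity correction.  Post-hoc paired t-tests are corrected with
the Benjamini–Hochberg step-up rule within each ANOVA's three-comparison
family.  Within-subject SEMs remove between-subject offset variability by
subject-centering and apply the √(k/(k−1)) small-sample correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RmAnovaResult",
    "TTestResult",
    "CorrelationResult",
    "rm_anova_1way",
    "paired_t",
    "two_sample_t",
    "pearson_corr",
    "bh_adjust",
    "stat_to_p",
    "within_subject_sem",
]


@dataclass(frozen=True)
class RmAnovaResult:
    f_stat: float
    df_num: int
    df_den: int
    p_raw: float
    ss_condition: float
    ss_subject: float
    ss_error: float
    degenerate: bool = False


@dataclass(frozen=True)
class TTestResult:
    t_stat: float
    df: float
    p_raw: float
    mean_difference: float
    p_adjusted: float | None = None
    degenerate: bool = False


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    df: int
    p_raw: float


def _as_complete_matrix(table) -> np.ndarray:
    x = np.asarray(table, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected an n-subjects × k-conditions table")
    if np.isnan(x).any():
        raise ValueError("missing cells: listwise-complete table required")
    return x


def rm_anova_1way(table) -> RmAnovaResult:
    """One-way repeated-measures ANOVA on an n × k table of condition means.

    Accepts a 2-D array or DataFrame with one row per subject and one column
    per condition.  Zero error variance with non-zero condition variance is
    reported as F = +inf, p = 0 and flagged ``degenerate``.
    """
    x = _as_complete_matrix(table)
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    grand = x.mean()
    ss_cond = n * float(((x.mean(axis=0) - grand) ** 2).sum())
    ss_subj = k * float(((x.mean(axis=1) - grand) ** 2).sum())
    ss_tot = float(((x - grand) ** 2).sum())
    ss_err = max(ss_tot - ss_cond - ss_subj, 0.0)
    df_num, df_den = k - 1, (k - 1) * (n - 1)
    if ss_err == 0.0:
        if ss_cond == 0.0:
            return RmAnovaResult(0.0, df_num, df_den, 1.0, ss_cond, ss_subj, ss_err)
        return RmAnovaResult(
            float("inf"), df_num, df_den, 0.0, ss_cond, ss_subj, ss_err,
            degenerate=True,
        )
    f = (ss_cond / df_num) / (ss_err / df_den)
    return RmAnovaResult(
        float(f), df_num, df_den, float(sps.f.sf(f, df_num, df_den)),
        ss_cond, ss_subj, ss_err,
    )


def paired_t(x, y) -> TTestResult:
    """Paired two-sided t-test: t = mean(d) / (sd(d)/√n), d = x − y, df = n−1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and paired by subject")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        if md == 0.0:
            return TTestResult(0.0, df, 1.0, 0.0)
        return TTestResult(float(np.sign(md)) * float("inf"), df, 0.0, md, degenerate=True)
    t = md / (sd / np.sqrt(n))
    return TTestResult(float(t), df, float(2.0 * sps.t.sf(abs(t), df)), md)


def two_sample_t(group_a, group_b, variant: str = "pooled") -> TTestResult:
    """Independent two-sample two-sided t-test.

    ``variant="pooled"`` is the classical Student form with a pooled
    variance estimate and df = n_a + n_b − 2; ``variant="welch"`` uses the
    unequal-variance statistic with Welch–Satterthwaite df.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    na, nb = a.size, b.size
    va, vb = float(a.var(ddof=1)), float(b.var(ddof=1))
    md = float(a.mean() - b.mean())
    if variant == "pooled":
        df: float = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    elif variant == "welch":
        se2 = va / na + vb / nb
        se = np.sqrt(se2)
        if se2 == 0.0:
            df = na + nb - 2
        else:
            df = se2**2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
            )
    else:
        raise ValueError("variant must be 'pooled' or 'welch'")
    if se == 0.0:
        if md == 0.0:
            return TTestResult(0.0, df, 1.0, 0.0)
        return TTestResult(float(np.sign(md)) * float("inf"), df, 0.0, md, degenerate=True)
    t = md / se
    return TTestResult(float(t), float(df), float(2.0 * sps.t.sf(abs(t), df)), md)


def pearson_corr(x, y) -> CorrelationResult:
    """Sample Pearson correlation; two-sided p via t = r·√(df/(1−r²)), df = n−2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length 1-D with n ≥ 3")
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValueError("correlation undefined: zero variance in an input")
    xc, yc = x - x.mean(), y - y.mean()
    r = float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))
    r = max(-1.0, min(1.0, r))
    df = x.size - 2
    if abs(r) == 1.0:
        return CorrelationResult(r, df, 0.0)
    t = r * np.sqrt(df / (1.0 - r * r))
    return CorrelationResult(r, df, float(2.0 * sps.t.sf(abs(t), df)))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    Sorted ascending, p_(i) becomes p_(i)·m/i; monotonicity is enforced from
    the largest rank downwards (cumulative minimum) and values are capped at
    1.  Output order matches input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(m)
    out[order] = adjusted
    return out


def stat_to_p(statistic: float, family: str, df) -> float:
    """p-value from a test statistic: two-sided for t, upper-tail for F."""
    if family == "t":
        df = float(df)
        if df <= 0:
            raise ValueError("t df must be positive")
        return float(2.0 * sps.t.sf(abs(statistic), df))
    if family == "F":
        dfn, dfd = df
        if dfn <= 0 or dfd <= 0:
            raise ValueError("F dfs must be positive")
        return float(sps.f.sf(statistic, dfn, dfd))
    raise ValueError("family must be 't' or 'F'")


def within_subject_sem(table) -> np.ndarray:
    """Within-subject standard error of each condition mean.

    Subject-centers the n × k table (subtract each subject's mean, add the
    grand mean), takes the per-condition SD of the centered values over √n,
    and applies the √(k/(k−1)) small-sample correction.  Appropriate for
    repeated-measures error bars: between-subject offset variability does
    not inflate it.
    """
    x = _as_complete_matrix(table)
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    centered = x - x.mean(axis=1, keepdims=True) + x.mean()
    sem = centered.std(axis=0, ddof=1) / np.sqrt(n)
    return sem * np.sqrt(k / (k - 1))
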
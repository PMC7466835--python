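"""Inferential statistics applied to edge strengths and sample
characteristics.

Thin, validated wrappers with a uniform :class:`StatResult` return type:
two-sample and paired t tests, one-way repeated-measures ANOVA with
partial eta squared, Pearson correlation, Pearson chi-square on a 2x2
table (no continuity correction), and Bonferroni adjustment.  t tests,
correlation and chi-square delegate to scipy; the within-subject ANOVA
is computed from its sums of squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DegenerateSignalError


@dataclass(frozen=True)
class StatResult:
    """A test statistic with df, two-tailed p, and optional effect size."""

    statistic: float
    df: tuple[float, ...]
    p_two_tailed: float
    effect_size: float | None = None
    label: str = ""

    def __post_init__(self):
        if not 0.0 <= self.p_two_tailed <= 1.0:
            raise ValueError(f"p = {self.p_two_tailed} outside [0, 1]")
        if any(d <= 0 for d in self.df):
            raise ValueError(f"non-positive df {self.df}")


def _as1d(x, name):
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size < 2:
        raise ValueError(f"{name} needs at least 2 observations")
    return arr


def two_sample_t(x, y, pooled: bool = True, label: str = "") -> StatResult:
    """Two-sample t test (Student's pooled-variance by default, Welch
    with ``pooled=False``)."""
    x, y = _as1d(x, "x"), _as1d(y, "y")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        raise DegenerateSignalError("both groups have zero variance")
    res = sps.ttest_ind(x, y, equal_var=pooled)
    return StatResult(
        statistic=float(res.statistic),
        df=(float(res.df),),
        p_two_tailed=float(res.pvalue),
        label=label,
    )


def paired_t(x, y, label: str = "") -> StatResult:
    """Paired t test with Cohen's d = mean(diff) / sd(diff)."""
    x, y = _as1d(x, "x"), _as1d(y, "y")
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    diff = x - y
    sd = diff.std(ddof=1)
    if sd == 0:
        raise DegenerateSignalError("zero difference variance")
    res = sps.ttest_rel(x, y)
    d = float(diff.mean() / sd)
    return StatResult(
        statistic=float(res.statistic),
        df=(float(x.size - 1),),
        p_two_tailed=float(res.pvalue),
        effect_size=d,
        label=label,
    )


def rm_anova(values, label: str = "") -> StatResult:
    """One-way repeated-measures ANOVA (condition within subjects).

    ``values`` is an (n_subjects x k_conditions) table (array or
    DataFrame) with no missing cells.  Returns
    F = MS_condition / MS_error with df (k-1, (k-1)(n-1)) and partial
    eta squared SS_condition / (SS_condition + SS_error).  No sphericity
    correction is applied.
    """
    if isinstance(values, pd.DataFrame):
        values = values.to_numpy(dtype=float)
    a = np.asarray(values, dtype=float)
    if a.ndim != 2:
        raise ValueError("values must be a 2-D subject x condition table")
    if np.isnan(a).any():
        raise ValueError("missing cells in the subject x condition table")
    n, k = a.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    grand = a.mean()
    ss_cond = n * ((a.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((a.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((a - grand) ** 2).sum()
    ss_error = ss_total - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_cond = ss_cond / df1
    ms_error = ss_error / df2
    if ms_error <= 1e-300:
        if ss_cond <= 1e-300:
            # purely subject-additive data: no condition effect at all
            return StatResult(0.0, (float(df1), float(df2)), 1.0, 0.0, label)
        raise DegenerateSignalError("zero error mean square")
    f = ms_cond / ms_error
    p = float(sps.f.sf(f, df1, df2))
    eta = ss_cond / (ss_cond + ss_error)
    return StatResult(
        statistic=float(f),
        df=(float(df1), float(df2)),
        p_two_tailed=p,
        effect_size=float(eta),
        label=label,
    )


def pearson_r(x, y, label: str = "") -> StatResult:
    """Pearson correlation with two-tailed p from the t transform."""
    x, y = _as1d(x, "x"), _as1d(y, "y")
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if x.std() == 0 or y.std() == 0:
        raise DegenerateSignalError("constant input to correlation")
    res = sps.pearsonr(x, y)
    return StatResult(
        statistic=float(res.statistic),
        df=(float(x.size - 2),),
        p_two_tailed=float(res.pvalue),
        label=label,
    )


def pearson_p_from_r(r: float, n: int) -> float:
    """Two-tailed p of a correlation r at sample size n,
    via t = r sqrt(n-2) / sqrt(1-r^2)."""
    if not -1 < r < 1:
        raise ValueError("r must be strictly inside (-1, 1)")
    if n < 3:
        raise ValueError("need n >= 3")
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
    return float(2 * sps.t.sf(abs(t), n - 2))


def chi_square_2x2(table, label: str = "") -> StatResult:
    """Pearson chi-square on a 2x2 count table, df = 1, no continuity
    correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in the 2x2 table")
    chi2, p, dof, _ = sps.chi2_contingency(t, correction=False)
    return StatResult(
        statistic=float(chi2),
        df=(float(dof),),
        p_two_tailed=float(p),
        label=label,
    )


def bonferroni(p_values, family_size: int | None = None) -> list[float]:
    """Bonferroni-adjusted p values: min(1, m * p)."""
    ps = [float(p) for p in np.atleast_1d(np.asarray(p_values, dtype=float))]
    m = len(ps) if family_size is None else int(family_size)
    if m < len(ps):
        raise ValueError("family_size must be >= number of p values")
    for p in ps:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p value {p} outside [0, 1]")
    return [min(1.0, m * p) for p in ps]
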
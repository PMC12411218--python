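"""Cohort-comparison statistics.

Thin, explicit wrappers around classical tests (one-way ANOVA, Student and
paired t, Pearson correlation, 2x2 chi-square) plus a noncentral-t power
iteration for two-sample sample-size planning.  Every function returns a
:class:`StatResult` so downstream reports serialize uniformly.

The chi-square test is Pearson's without continuity correction by default,
and the two-sample t-test pools variances (Student), matching the degrees of
freedom convention df = n_a + n_b - 2 used throughout the immune-index
comparisons; Welch and Yates variants are available by flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "StatResult",
    "PowerSpec",
    "oneway_anova",
    "two_sample_t",
    "paired_t",
    "pearson_correlation",
    "chi2_2x2",
    "power_two_sample_t",
    "sample_size_two_sample_t",
]


@dataclass(frozen=True)
class StatResult:
    """A test statistic with its degrees of freedom, p-value and effect size."""

    test: str
    statistic: float
    df: tuple[int, ...]
    p_value: float
    effect_size: float | None = None
    effect_size_name: str | None = None
    n: tuple[int, ...] = field(default_factory=tuple)
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": float(self.statistic),
            "df": list(self.df),
            "p_value": float(self.p_value),
            "effect_size": None if self.effect_size is None else float(self.effect_size),
            "effect_size_name": self.effect_size_name,
            "n": list(self.n),
            **self.extra,
        }


@dataclass(frozen=True)
class PowerSpec:
    """Design parameters for a two-sided two-sample t-test power analysis."""

    effect_size: float
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self) -> None:
        if self.effect_size <= 0:
            raise ValueError("effect_size (Cohen's d) must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not self.alpha < self.power < 1:
            raise ValueError("power must be in (alpha, 1)")


def _as_groups(groups) -> list[np.ndarray]:
    out = [np.asarray(g, dtype=float).ravel() for g in groups]
    if any(not np.all(np.isfinite(g)) for g in out):
        raise ValueError("non-finite values in input")
    return out


def oneway_anova(groups) -> StatResult:
    """Classical one-way fixed-effects ANOVA across k groups.

    Reports F with df = (k-1, N-k) and Cohen's f computed from the
    between/within sums of squares.
    """
    gs = _as_groups(groups)
    k = len(gs)
    if k < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(gs):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than 2 observations")
    n_total = sum(g.size for g in gs)
    grand = np.concatenate(gs).mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df1, df2 = k - 1, n_total - k
    if ssw == 0:
        f_stat = math.inf if ssb > 0 else 0.0
        p = 0.0 if ssb > 0 else 1.0
    else:
        f_stat = (ssb / df1) / (ssw / df2)
        p = float(sps.f.sf(f_stat, df1, df2))
    cohens_f = math.sqrt(ssb / ssw) if ssw > 0 else math.inf
    return StatResult(
        test="oneway_anova",
        statistic=float(f_stat),
        df=(df1, df2),
        p_value=p,
        effect_size=cohens_f,
        effect_size_name="cohens_f",
        n=tuple(g.size for g in gs),
    )


def two_sample_t(a, b, *, welch: bool = False) -> StatResult:
    """Two-sided two-sample t-test, pooled variance by default (df = n_a+n_b-2)."""
    a, b = _as_groups([a, b])
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs >= 2 observations")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0 and a.mean() == b.mean():
        # degenerate-variance convention: identical constants -> no evidence
        df = a.size + b.size - 2
        return StatResult("two_sample_t", 0.0, (df,), 1.0, 0.0, "cohens_d", (a.size, b.size))
    res = sps.ttest_ind(a, b, equal_var=not welch)
    df = float(res.df)
    sp = math.sqrt(
        ((a.size - 1) * np.var(a, ddof=1) + (b.size - 1) * np.var(b, ddof=1))
        / (a.size + b.size - 2)
    )
    d = (a.mean() - b.mean()) / sp if sp > 0 else math.inf
    return StatResult(
        test="welch_t" if welch else "two_sample_t",
        statistic=float(res.statistic),
        df=(int(df),) if float(df).is_integer() else (int(round(df)),),
        p_value=float(res.pvalue),
        effect_size=float(d),
        effect_size_name="cohens_d",
        n=(a.size, b.size),
        extra={"df_exact": df},
    )


def paired_t(a, b) -> StatResult:
    """Two-sided paired t-test on matched observations (df = n-1)."""
    a, b = _as_groups([a, b])
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise ValueError("need >= 2 pairs")
    diff = a - b
    if np.var(diff, ddof=1) == 0:
        stat, p = (0.0, 1.0) if diff.mean() == 0 else (math.copysign(math.inf, diff.mean()), 0.0)
    else:
        res = sps.ttest_rel(a, b)
        stat, p = float(res.statistic), float(res.pvalue)
    sd = float(np.std(diff, ddof=1))
    d = diff.mean() / sd if sd > 0 else (0.0 if diff.mean() == 0 else math.inf)
    return StatResult(
        "paired_t", stat, (a.size - 1,), p, float(d), "cohens_d_z", (a.size,)
    )


def pearson_correlation(x, y) -> StatResult:
    """Pearson r with a two-sided p from the t transform, df = n-2."""
    x, y = _as_groups([x, y])
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance in input")
    res = sps.pearsonr(x, y)
    return StatResult(
        "pearson_correlation",
        float(res.statistic),
        (x.size - 2,),
        float(res.pvalue),
        float(res.statistic),
        "r",
        (x.size,),
    )


def chi2_2x2(counts, *, continuity: bool = False) -> StatResult:
    """Pearson chi-square on a 2x2 contingency table, df = 1.

    Default is the uncorrected statistic N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d));
    Yates continuity correction by flag.
    """
    table = np.asarray(counts, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("counts must be a 2x2 table")
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("chi-square undefined: a row or column margin is zero")
    stat, p, dof, _ = sps.chi2_contingency(table, correction=continuity)
    n_total = table.sum()
    phi = math.sqrt(stat / n_total)
    return StatResult(
        "chi2_2x2",
        float(stat),
        (int(dof),),
        float(p),
        phi,
        "phi",
        tuple(int(v) for v in table.sum(axis=1)),
    )


def power_two_sample_t(n_per_group: int, d: float, alpha: float = 0.05) -> float:
    """Exact power of the two-sided two-sample t-test at n per group.

    Noncentral-t with noncentrality d*sqrt(n/2) and df = 2n-2.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    df = 2 * n_per_group - 2
    nc = d * math.sqrt(n_per_group / 2.0)
    t_crit = sps.t.ppf(1 - alpha / 2, df)
    return float(1 - sps.nct.cdf(t_crit, df, nc) + sps.nct.cdf(-t_crit, df, nc))


def sample_size_two_sample_t(spec: PowerSpec, n_max: int = 100_000) -> int:
    """Smallest per-group n reaching the specified power for a two-sided test."""
    n = 2
    while n <= n_max:
        if power_two_sample_t(n, spec.effect_size, spec.alpha) >= spec.power:
            return n
        n += 1
    raise ValueError("no n <= n_max reaches the requested power")
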
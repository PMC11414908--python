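"""Shared nonparametric statistics used across the pipeline.

Thin, uniformly-typed wrappers around scipy/statsmodels: Holm-Bonferroni
step-down adjustment, one-sided Wilcoxon sign-rank, Wilcoxon rank-sum
(Mann-Whitney), Kruskal-Wallis, two-sample Kolmogorov-Smirnov, and Pearson
correlation with R^2. Small samples use exact null distributions where scipy
provides them (sign-rank and rank-sum below n = 25, KS via method='auto');
larger samples fall back to the usual asymptotics with continuity correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "holm_bonferroni",
    "signrank_one_sided",
    "rank_sum",
    "kruskal_wallis",
    "ks_two_sample",
    "pearson_with_r2",
    "r_squared",
]

EXACT_N = 25  # below this, exact null distributions are used where feasible


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    df: float | tuple | None = None
    n: int | None = None
    sidedness: str = "two-sided"
    note: str = ""

    def __post_init__(self) -> None:
        p = self.p_value
        if np.isfinite(p) and not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value {p} outside [0, 1]")


def holm_bonferroni(p_values, alpha: float = 0.05):
    """Holm's step-down adjustment.

    Returns ``(reject, adjusted)``: boolean rejections at ``alpha`` and
    monotone adjusted p-values (max-accumulated (m-i+1)*p_(i), capped at 1).
    Empty input yields empty arrays.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if not np.all(np.isfinite(p)):
        raise ValueError("p-values must be finite")
    reject, adjusted, _, _ = multipletests(p, alpha=alpha, method="holm")
    return reject, adjusted


def signrank_one_sided(x, y=None, alternative: str = "greater") -> TestResult:
    """One-sided Wilcoxon sign-rank test on paired samples (or differences).

    Zero differences are dropped (standard Wilcoxon convention) and counted
    in the result note; if all differences are zero the test returns p = 1,
    flagged. Exact null distribution for n <= 25 without ties in |d|;
    otherwise normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    nz = d[d != 0]
    n = nz.size
    if n == 0:
        return TestResult(0.0, 1.0, n=0, sidedness=alternative,
                          note="all paired differences zero")
    ties = np.unique(np.abs(nz)).size < n
    method = "exact" if (n <= EXACT_N and not ties) else "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sps.wilcoxon(
            nz, alternative=alternative, method=method, correction=(method == "approx")
        )
    note = f"{d.size - n} zero differences dropped" if d.size != n else ""
    if ties and n <= EXACT_N:
        note = (note + "; " if note else "") + "ties in |d|: normal approximation"
    return TestResult(float(res.statistic), float(res.pvalue), n=n,
                      sidedness=alternative, note=note)


def rank_sum(x, y, alternative: str = "two-sided") -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney U) test; exact for small tie-free samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (max(x.size, y.size) < EXACT_N and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    return TestResult(float(res.statistic), float(res.pvalue),
                      n=x.size + y.size, sidedness=alternative)


def kruskal_wallis(*groups) -> TestResult:
    """Kruskal-Wallis H test across two or more groups."""
    if len(groups) < 2:
        raise ValueError("kruskal_wallis needs at least two groups")
    res = sps.kruskal(*groups)
    return TestResult(float(res.statistic), float(res.pvalue),
                      df=len(groups) - 1, n=sum(len(g) for g in groups))


def ks_two_sample(x, y, jitter_seed=None) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test on continuous samples.

    Latencies are treated as continuous; when ties are present and an exact
    small-sample path would otherwise be taken, sub-microsecond uniform
    jitter (seeded via ``jitter_seed``) breaks them, as documented.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if jitter_seed is not None:
        pooled = np.concatenate([x, y])
        if np.unique(pooled).size < pooled.size:
            rng = np.random.default_rng(jitter_seed)
            x = x + rng.uniform(-5e-4, 5e-4, x.size)
            y = y + rng.uniform(-5e-4, 5e-4, y.size)
    res = sps.ks_2samp(x, y, method="auto")
    return TestResult(float(res.statistic), float(res.pvalue), n=x.size + y.size)


def pearson_with_r2(x, y) -> TestResult:
    """Pearson product-moment correlation with R^2 and two-sided t-test p.

    Returns a flagged NaN result when either input has zero variance or
    n < 3 (correlation undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3 or np.var(x) == 0 or np.var(y) == 0:
        return TestResult(float("nan"), float("nan"), n=x.size,
                          note="correlation undefined (zero variance or n < 3)")
    r, p = sps.pearsonr(x, y)
    return TestResult(float(r), float(p), n=x.size)


def r_squared(result: TestResult) -> float:
    """Coefficient of determination for a Pearson TestResult."""
    return float(result.statistic**2)
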
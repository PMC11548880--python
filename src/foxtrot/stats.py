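"""Self-contained statistical kernel.

Nested-OLS F-test, likelihood-ratio chi-square test, paired and Welch
two-sample t procedures, and a seeded percentile bootstrap. These back the
model-comparison and contrast steps of the pipeline: per-individual
estimates summarised with paired tests stand in for the mixed-effects
formulation often used on such data (each bird is its own block, so the
paired contrast targets the same estimand without a REML engine).

All tests are two-sided and report raw p-values; no multiplicity
correction is applied anywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "f_test_nested",
    "lrt_chi2",
    "paired_t",
    "two_sample_t",
    "bootstrap_ci",
]

_RSS_TOL = 1e-9


@dataclass
class TestResult:
    """Outcome of a hypothesis test.

    ``df`` is a single number for t/chi-square tests and a ``(num, den)``
    pair for F-tests. ``estimate`` and the CI bounds are NaN where the
    procedure does not produce an effect estimate. ``flag`` carries
    degenerate-case annotations (e.g. zero-variance input).
    """

    statistic: float
    df: float | tuple[float, float]
    p_value: float
    estimate: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    flag: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def f_test_nested(rss0: float, df0: int, rss1: float, df1: int, n: int) -> TestResult:
    """F-test comparing nested OLS models.

    Model 0 (``df0`` parameters, residual sum of squares ``rss0``) is nested
    in model 1 (``df1`` > ``df0`` parameters, ``rss1`` <= ``rss0``), both fit
    to the same ``n`` observations.

    F = ((rss0 - rss1) / (df1 - df0)) / (rss1 / (n - df1))
    """
    if df1 <= df0:
        raise ValueError("larger model must have more parameters than the nested one")
    if n <= df1:
        raise ValueError(f"need n > {df1} observations, got {n}")
    if rss1 > rss0 * (1.0 + _RSS_TOL) + _RSS_TOL:
        raise ValueError("nested model cannot fit better: rss1 > rss0")
    rss1 = min(rss1, rss0)
    dfn = df1 - df0
    dfd = n - df1
    if rss1 == 0.0:
        if rss0 == 0.0:
            return TestResult(statistic=0.0, df=(dfn, dfd), p_value=1.0, flag="both models exact")
        return TestResult(statistic=float("inf"), df=(dfn, dfd), p_value=0.0, flag="perfect fit")
    f = ((rss0 - rss1) / dfn) / (rss1 / dfd)
    p = float(sps.f.sf(f, dfn, dfd))
    return TestResult(statistic=float(f), df=(dfn, dfd), p_value=p)


def lrt_chi2(loglik0: float, loglik1: float, df_diff: int) -> TestResult:
    """Likelihood-ratio test of a nested model pair.

    The statistic 2*(loglik1 - loglik0) is referred to a chi-square
    distribution with ``df_diff`` degrees of freedom.
    """
    if df_diff < 1:
        raise ValueError("df_diff must be >= 1")
    if loglik1 < loglik0 - 1e-9 * max(1.0, abs(loglik0)):
        raise ValueError("larger model has lower log-likelihood; models are not nested or fit failed")
    stat = max(0.0, 2.0 * (loglik1 - loglik0))
    p = float(sps.chi2.sf(stat, df_diff))
    return TestResult(statistic=stat, df=float(df_diff), p_value=p)


def _t_ci(estimate: float, se: float, df: float, level: float = 0.95) -> tuple[float, float]:
    half = sps.t.ppf(0.5 + level / 2.0, df) * se
    return estimate - half, estimate + half


def paired_t(differences: Sequence[float]) -> TestResult:
    """One-sample t-test of paired differences against zero.

    Parameters
    ----------
    differences : sequence of float
        Per-block difference values (e.g. per-bird quick minus slow share).
        At least 3 values required.
    """
    d = np.asarray(differences, dtype=float)
    if d.size < 3:
        raise ValueError("paired t-test needs at least 3 differences")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    df = d.size - 1
    if sd == 0.0:
        if mean == 0.0:
            return TestResult(0.0, float(df), 1.0, estimate=0.0, ci_low=0.0, ci_high=0.0,
                              flag="zero variance")
        return TestResult(float("inf"), float(df), 0.0, estimate=mean, ci_low=mean,
                          ci_high=mean, flag="zero variance, nonzero mean")
    se = sd / np.sqrt(d.size)
    t = mean / se
    p = float(2.0 * sps.t.sf(abs(t), df))
    lo, hi = _t_ci(mean, se, df)
    return TestResult(float(t), float(df), p, estimate=mean, ci_low=lo, ci_high=hi)


def two_sample_t(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Welch two-sample t-test for a difference in means (a minus b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("two-sample t-test needs at least 3 values per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    est = float(a.mean() - b.mean())
    if va == 0.0 and vb == 0.0:
        if est == 0.0:
            return TestResult(0.0, float(a.size + b.size - 2), 1.0, estimate=0.0,
                              ci_low=0.0, ci_high=0.0, flag="zero variance")
        return TestResult(float("inf"), float(a.size + b.size - 2), 0.0, estimate=est,
                          ci_low=est, ci_high=est, flag="zero variance, nonzero mean")
    se2 = va / a.size + vb / b.size
    se = float(np.sqrt(se2))
    # Welch-Satterthwaite degrees of freedom
    df = se2**2 / ((va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1))
    t = est / se
    p = float(2.0 * sps.t.sf(abs(t), df))
    lo, hi = _t_ci(est, se, df)
    return TestResult(float(t), float(df), p, estimate=est, ci_low=lo, ci_high=hi)


def bootstrap_ci(
    values: Sequence[float],
    statistic: Callable[[np.ndarray], float] = np.mean,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Seeded percentile bootstrap confidence interval.

    Resamples ``values`` with replacement ``n_boot`` times (>= 200) and
    returns the percentile interval of the statistic. Deterministic for a
    fixed seed.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 1:
        raise ValueError("bootstrap needs at least one value")
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200 for a stable percentile interval")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    boot = np.apply_along_axis(statistic, 1, x[idx])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(boot, [alpha, 1.0 - alpha])
    return float(lo), float(hi)
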
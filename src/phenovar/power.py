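"""CV-parameterized power and sample size for the two-sided two-sample t-test.

With the test-group mean written as a multiple k of the control-group mean
(mu1 = k * mu0) and equal standard deviations sigma in both groups, the
standardized effect size becomes

    Delta = (mu1 - mu0) / sigma = (k - 1) / CV,   CV = sigma / mu0,

so sample-size planning needs only the fold change k and the control group's
coefficient of variation.  Power of the pooled two-sample t-test with n
animals per group follows the noncentral t distribution with df = 2n - 2 and
noncentrality delta = Delta * sqrt(n / 2); the minimum per-group size is the
smallest integer n >= min_n whose power reaches 1 - beta.  Because |Delta| is
the same for k and 2 - k, sample sizes are symmetric around k = 1 (a 20%
increase costs as many animals as a 20% decrease).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PowerQuery",
    "SampleSizeTable",
    "TABLE_K_GRID",
    "TABLE_CV_GRID",
    "effect_size",
    "t_test_power",
    "normal_approx_power",
    "sample_size",
    "generate_sample_size_table",
    "mc_power_oracle",
]

#: Default fold-change grid: 1.10 to 2.00 in steps of 0.05.
TABLE_K_GRID: tuple[float, ...] = tuple(round(1.10 + 0.05 * i, 2) for i in range(19))
#: Default CV grid: 0.03, 0.05, then 0.10 to 0.60 in steps of 0.05, 0.70, 0.80, 0.90.
TABLE_CV_GRID: tuple[float, ...] = (0.03, 0.05) + tuple(
    round(0.10 + 0.05 * i, 2) for i in range(11)
) + (0.70, 0.80, 0.90)

#: Per-group sizes of 2 are statistically admissible (df = 2) but at least
#: 3-5 animals per group are advisable given within-strain variability.
MIN_ADVISABLE_GROUP_SIZE = 3


@dataclass(frozen=True)
class PowerQuery:
    """One sample-size question: fold change k, control CV, error rates."""

    k: float
    cv: float
    alpha: float = 0.05
    beta: float = 0.2
    min_n: int = 2

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be > 0")
        if self.k == 1:
            raise ValueError("k = 1 means no effect; no finite sample size")
        if self.cv <= 0:
            raise ValueError("cv must be > 0")
        if not (0 < self.alpha < 1 and 0 < self.beta < 1):
            raise ValueError("alpha and beta must lie in (0, 1)")
        if self.min_n < 2:
            raise ValueError("min_n must be >= 2 (df = 2n - 2 >= 2)")


@dataclass(frozen=True)
class SampleSizeTable:
    """Integer per-group sample sizes over a k x CV grid (rows = CV)."""

    k_grid: tuple[float, ...]
    cv_grid: tuple[float, ...]
    n: np.ndarray  # shape (len(cv_grid), len(k_grid))

    def cell(self, k: float, cv: float) -> int:
        i = self.cv_grid.index(cv)
        j = self.k_grid.index(k)
        return int(self.n[i, j])

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.n, columns=[f"{k:.2f}" for k in self.k_grid])
        df.insert(0, "CV", [f"{cv:.2f}" for cv in self.cv_grid])
        return df


def effect_size(k: float, cv: float) -> float:
    """Standardized effect size Delta = (k - 1) / CV."""
    if cv <= 0:
        raise ValueError("cv must be > 0")
    return (k - 1.0) / cv


def t_test_power(n: int, delta: float, alpha: float = 0.05) -> float:
    """Exact power of the two-sided pooled two-sample t-test.

    ``n`` animals per group, true standardized difference ``delta``; under the
    alternative the t statistic is noncentral t with df = 2n - 2 and
    noncentrality delta * sqrt(n / 2).  Power = P(|T'| > t_{1-alpha/2, df}).
    """
    if n < 2:
        raise ValueError("n must be >= 2 per group (df = 2n - 2 >= 2)")
    df = 2 * n - 2
    ncp = delta * math.sqrt(n / 2.0)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))


def normal_approx_power(n: int, delta: float, alpha: float = 0.05) -> float:
    """Large-sample normal approximation Phi(d - z) + Phi(-d - z), d = delta*sqrt(n/2)."""
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    d = delta * math.sqrt(n / 2.0)
    return float(stats.norm.cdf(d - z) + stats.norm.cdf(-d - z))


def sample_size(query: PowerQuery) -> int:
    """Smallest integer per-group n with t-test power >= 1 - beta.

    Starts from the normal-approximation solution, then walks the integer
    lattice with the exact noncentral-t power in both directions, so the
    answer never depends on how a continuous root would round.
    """
    delta = abs(effect_size(query.k, query.cv))
    target = 1.0 - query.beta
    z = stats.norm.ppf(1.0 - query.alpha / 2.0) + stats.norm.ppf(target)
    n = max(query.min_n, math.ceil(2.0 * (z / delta) ** 2))
    while t_test_power(n, delta, query.alpha) < target:
        n += 1
    while n > query.min_n and t_test_power(n - 1, delta, query.alpha) >= target:
        n -= 1
    return n


def generate_sample_size_table(
    k_grid: Sequence[float] | None = None,
    cv_grid: Sequence[float] | None = None,
    alpha: float = 0.05,
    beta: float = 0.2,
    min_n: int = 2,
) -> SampleSizeTable:
    """Per-group sample sizes for every (CV, k) pair; defaults give the
    standard 16 x 19 planning grid."""
    k_grid = tuple(k_grid) if k_grid is not None else TABLE_K_GRID
    cv_grid = tuple(cv_grid) if cv_grid is not None else TABLE_CV_GRID
    if not k_grid or not cv_grid:
        raise ValueError("grids must be non-empty")
    n = np.empty((len(cv_grid), len(k_grid)), dtype=int)
    for i, cv in enumerate(cv_grid):
        for j, k in enumerate(k_grid):
            n[i, j] = sample_size(PowerQuery(k=k, cv=cv, alpha=alpha, beta=beta, min_n=min_n))
    return SampleSizeTable(k_grid=k_grid, cv_grid=cv_grid, n=n)


def mc_power_oracle(n: int, delta: float, alpha: float = 0.05,
                    reps: int = 100_000, seed: int = 0) -> float:
    """Monte-Carlo power of the pooled two-sample t-test (test oracle).

    Simulates ``reps`` pairs of unit-variance normal samples with means 0 and
    ``delta``, and returns the rejection fraction of the two-sided pooled
    t-test at ``alpha``.  Fully reproducible given ``seed``.
    """
    if reps < 1000:
        raise ValueError("reps must be >= 1000 for a meaningful estimate")
    rng = np.random.default_rng(seed)
    rejections = 0
    chunk = max(1, min(reps, 20_000_000 // max(n, 1)))
    df = 2 * n - 2
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    done = 0
    while done < reps:
        b = min(chunk, reps - done)
        x = rng.standard_normal((b, n))
        y = rng.standard_normal((b, n)) + delta
        mx, my = x.mean(axis=1), y.mean(axis=1)
        vx, vy = x.var(axis=1, ddof=1), y.var(axis=1, ddof=1)
        sp = np.sqrt((vx + vy) / 2.0)
        t = (my - mx) / (sp * math.sqrt(2.0 / n))
        rejections += int(np.count_nonzero(np.abs(t) > tcrit))
        done += b
    return rejections / reps
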
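"""Group statistics for peak frequencies.

Two tests cover the statistical stage of the analysis: a Lilliefors
normality check (Kolmogorov–Smirnov against a normal with estimated mean
and SD, with Monte-Carlo critical values so the p-value is exact-in-the-
limit at any sample size) and a rank-based two-group comparison of peak
frequencies.  The groups being compared have unequal sizes, so the default
comparison is the two-sided Mann–Whitney rank-sum test (exact enumeration
for small samples, normal approximation with tie correction otherwise);
a paired Wilcoxon signed-rank variant is available behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats as sst

__all__ = ["TestResult", "GroupSummary", "lilliefors", "rank_compare", "summarize_group"]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n1: int
    n2: int = 0
    alpha: float = 0.01
    all_tied: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass(frozen=True)
class GroupSummary:
    """Mean ± SD summary of one cohort × band cell group."""

    cohort: str
    band: str
    values: tuple

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values)) if self.values else float("nan")

    @property
    def sd(self) -> float:
        # n-1 denominator, as in "Mean±SD" reporting
        return float(np.std(self.values, ddof=1)) if len(self.values) > 1 else float("nan")

    def __str__(self) -> str:
        return f"{self.cohort}/{self.band}: {self.mean:.2f}±{self.sd:.2f} Hz (n={self.n})"


def summarize_group(cohort: str, band: str, values) -> GroupSummary:
    values = tuple(float(v) for v in values)
    if any(v <= 0 for v in values):
        raise ValueError("peak frequencies must be positive")
    return GroupSummary(cohort=cohort, band=band, values=values)


def _lilliefors_stat(x: np.ndarray) -> float:
    """Sup-norm distance of the ECDF from N(mean, sd²) with estimated moments."""
    n = x.size
    xs = np.sort(x)
    z = (xs - xs.mean()) / xs.std(ddof=1)
    cdf = sst.norm.cdf(z)
    up = np.arange(1, n + 1) / n - cdf
    down = cdf - np.arange(0, n) / n
    return float(max(up.max(), down.max()))


def _lilliefors_stat_matrix(x: np.ndarray) -> np.ndarray:
    """Row-wise Lilliefors statistic for a (replicates, n) matrix."""
    n = x.shape[1]
    xs = np.sort(x, axis=1)
    z = (xs - xs.mean(axis=1, keepdims=True)) / xs.std(axis=1, ddof=1, keepdims=True)
    cdf = sst.norm.cdf(z)
    grid_hi = np.arange(1, n + 1) / n
    grid_lo = np.arange(0, n) / n
    return np.maximum((grid_hi - cdf).max(axis=1), (cdf - grid_lo).max(axis=1))


@lru_cache(maxsize=32)
def _null_table(n: int, n_mc: int, seed: int) -> np.ndarray:
    """Sorted Monte-Carlo null distribution of the statistic at sample size n.

    The null distribution is parameter-free (location/scale are estimated),
    so standard-normal draws suffice.  Cached because calibration studies
    reuse the same (n, n_mc, seed) many times.
    """
    rng = np.random.default_rng(seed)
    draws = rng.standard_normal((n_mc, n))
    return np.sort(_lilliefors_stat_matrix(draws))


def lilliefors(samples, n_mc: int = 10000, seed: int = 0, alpha: float = 0.05) -> TestResult:
    """Lilliefors normality test with Monte-Carlo p-value.

    The p-value is the fraction of ``n_mc`` simulated standard-normal
    samples of the same size whose statistic is at least the observed one;
    it is deterministic under a fixed seed.

    Raises
    ------
    ValueError
        For fewer than 4 observations or a zero-variance sample.
    """
    x = np.asarray(samples, dtype=np.float64)
    if x.size < 4:
        raise ValueError("Lilliefors test requires at least 4 observations")
    if np.ptp(x) == 0:
        raise ValueError("degenerate sample: zero variance")
    d = _lilliefors_stat(x)
    table = _null_table(int(x.size), int(n_mc), int(seed))
    # fraction of null statistics >= observed
    p = 1.0 - np.searchsorted(table, d, side="left") / table.size
    return TestResult(
        statistic=d, p_value=float(p), method="lilliefors_mc", n1=int(x.size), alpha=alpha
    )


def rank_compare(group_a, group_b, alpha: float = 0.01, paired: bool = False) -> TestResult:
    """Two-sided rank comparison of two groups of peak frequencies.

    Unpaired (default): Mann–Whitney rank-sum with exact enumeration when
    the pooled size is at most 12 and there are no ties, otherwise the
    normal approximation with tie correction.  ``paired=True`` runs the
    Wilcoxon signed-rank test instead (requires equal sizes).
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison requires equal group sizes")
        if np.all(a == b):
            return TestResult(0.0, 1.0, "wilcoxon_signed_rank", a.size, b.size, alpha, True)
        res = sst.wilcoxon(a, b, alternative="two-sided")
        return TestResult(float(res.statistic), float(res.pvalue),
                          "wilcoxon_signed_rank", int(a.size), int(b.size), alpha)

    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        warnings.warn("all values tied across both groups; p = 1", stacklevel=2)
        return TestResult(float(a.size * b.size / 2), 1.0, "rank_sum", a.size, b.size, alpha, True)
    has_ties = np.unique(pooled).size < pooled.size
    if a.size + b.size <= 12 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sst.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method=f"rank_sum_{method}",
        n1=int(a.size),
        n2=int(b.size),
        alpha=alpha,
    )
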
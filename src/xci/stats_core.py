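"""Exact and resampling statistics shared by every pipeline stage.

All allelic-imbalance calls in this package reduce to a handful of
primitives: exact binomial tests against an empirical error bound, exact
Wilcoxon signed-rank tests on paired per-tissue proportions, FDR control
(Benjamini-Hochberg, optionally Storey's pi0-adjusted q-values), Jeffreys
binomial intervals, and a generic label-permutation engine. They are
collected here so that every stage tests against the same, well-tested
definitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Literal, Sequence

import numpy as np
from scipy import stats as sps

Sided = Literal["greater", "less", "two_sided"]

_SIDED = ("greater", "less", "two_sided")


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test."""

    statistic: float
    p_value: float
    sided: Sided
    n: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class FDRResult:
    """q-values aligned to the input p-value vector."""

    q_values: np.ndarray
    method: Literal["BH", "storey"]
    pi0: float = 1.0


def _check_sided(sided: str) -> None:
    if sided not in _SIDED:
        raise ValueError(f"sided must be one of {_SIDED}, got {sided!r}")


def binom_test_exact(k: int, n: int, p0: float, sided: Sided = "two_sided") -> TestResult:
    """Exact binomial test of k successes in n trials against success
    probability ``p0``.

    The two-sided p-value follows the minimum-likelihood convention (as in
    R's ``binom.test``): the sum of probabilities of all outcomes no more
    likely than the observed one. For ``p0 = 0.5`` this coincides with
    doubling the smaller tail.
    """
    _check_sided(sided)
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= k <= n):
        raise ValueError(f"k={k} outside [0, {n}]")
    if not (0.0 < p0 < 1.0):
        raise ValueError("p0 must be in (0, 1)")
    alternative = {"greater": "greater", "less": "less", "two_sided": "two-sided"}[sided]
    p = sps.binomtest(k, n, p0, alternative=alternative).pvalue
    return TestResult(statistic=float(k), p_value=min(1.0, float(p)), sided=sided, n=n)


def _signed_rank_distribution(double_ranks: np.ndarray) -> np.ndarray:
    """Probability mass of W+ (sum of positive doubled ranks) under the
    equiprobable sign-flip null. Doubling the midranks keeps the support on
    the integers even with tied magnitudes."""
    total = int(double_ranks.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in double_ranks:
        r = int(r)
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: total + 1 - r]
        pmf = 0.5 * (pmf + shifted)
    return pmf


def wilcoxon_signed_rank_exact(
    diffs: Sequence[float],
    sided: Sided = "two_sided",
    exact_max_n: int = 30,
) -> TestResult:
    """Wilcoxon signed-rank test on paired differences.

    Zero differences are discarded. For n <= ``exact_max_n`` the null
    distribution of W+ is enumerated exactly under the 2^n sign-flip null
    (ties in magnitude handled through midranks); beyond that a normal
    approximation with tie correction and continuity correction is used.
    """
    _check_sided(sided)
    d = np.asarray(diffs, dtype=float)
    if np.any(np.isnan(d)):
        raise ValueError("NaN differences not allowed")
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero: no information")

    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= exact_max_n:
        double_ranks = np.round(2 * ranks).astype(int)
        pmf = _signed_rank_distribution(double_ranks)
        w2 = int(round(2 * w_plus))
        p_greater = float(pmf[w2:].sum())
        p_less = float(pmf[: w2 + 1].sum())
        if sided == "greater":
            p = p_greater
        elif sided == "less":
            p = p_less
        else:
            p = min(1.0, 2.0 * min(p_greater, p_less))
    else:
        mean = n * (n + 1) / 4.0
        # variance with tie correction over groups of tied magnitudes
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = ((counts**3 - counts) / 48.0).sum()
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        sd = math.sqrt(var)
        if sided == "greater":
            p = float(sps.norm.sf((w_plus - 0.5 - mean) / sd))
        elif sided == "less":
            p = float(sps.norm.cdf((w_plus + 0.5 - mean) / sd))
        else:
            z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / sd
            p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return TestResult(statistic=w_plus, p_value=min(1.0, p), sided=sided, n=n)


def _bh_qvalues(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def estimate_pi0(p: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Storey's estimate of the proportion of true nulls, smoothing
    pi0(lambda) over a lambda grid with a cubic spline and reading off the
    value at the largest lambda."""
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    m = p.size
    pi0_l = np.array([(p > lam).sum() / (m * (1 - lam)) for lam in lambdas])
    if np.all(pi0_l >= 1):
        return 1.0
    from scipy.interpolate import CubicSpline

    spline = CubicSpline(lambdas, pi0_l)
    pi0 = float(spline(lambdas[-1]))
    return float(min(max(pi0, 1.0 / m), 1.0))


def fdr_qvalues(pvals: Sequence[float], method: Literal["BH", "storey"] = "BH") -> FDRResult:
    """q-values controlling the FDR across the input p-values.

    ``BH`` is the Benjamini-Hochberg step-up; ``storey`` scales the BH
    q-values by an estimated null proportion pi0.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return FDRResult(q_values=p.copy(), method=method)
    if np.any(np.isnan(p)):
        raise ValueError("NaN p-values not allowed")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = _bh_qvalues(p)
    if method == "BH":
        return FDRResult(q_values=q, method="BH")
    if method == "storey":
        pi0 = estimate_pi0(p)
        return FDRResult(q_values=np.minimum(q * pi0, 1.0), method="storey", pi0=pi0)
    raise ValueError(f"unknown FDR method {method!r}")


def jeffreys_interval(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Jeffreys binomial confidence interval: central quantiles of
    Beta(k + 1/2, n - k + 1/2), with the boundary convention lo = 0 when
    k = 0 and hi = 1 when k = n."""
    if n < 1 or not (0 <= k <= n):
        raise ValueError(f"invalid (k={k}, n={n})")
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    alpha = 1.0 - level
    dist = sps.beta(k + 0.5, n - k + 0.5)
    lo = 0.0 if k == 0 else float(dist.ppf(alpha / 2))
    hi = 1.0 if k == n else float(dist.ppf(1 - alpha / 2))
    return lo, hi


def permutation_pvalue(
    observed_stat: float | np.ndarray,
    stat_fn: Callable[[np.ndarray], float | np.ndarray],
    labels: Sequence,
    n_perm: int = 10_000,
    seed: int | None = None,
    alternative: Literal["greater", "less"] = "greater",
    exhaustive: bool = False,
) -> float | np.ndarray:
    """Label-permutation p-value for ``observed_stat``.

    Shuffles preserve the two label-class sizes. The Monte-Carlo estimator
    uses the add-one rule p = (1 + #{permuted at least as extreme}) /
    (1 + n_perm), which never returns 0. With ``exhaustive=True`` all
    distinct relabelings are enumerated and the exact conditional p-value
    (which includes the identity arrangement) is returned instead.

    ``stat_fn`` may return a vector of statistics evaluated on the same
    shuffle (e.g. one per chromatin state); the permutation p is then
    computed elementwise over a shared set of shuffles.
    """
    labels = np.asarray(labels)
    classes, class_idx = np.unique(labels, return_inverse=True)
    if classes.size != 2:
        raise ValueError(f"labels must have exactly two classes, got {classes.size}")
    observed = np.atleast_1d(np.asarray(observed_stat, dtype=float))
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")

    def extreme(stat: np.ndarray) -> np.ndarray:
        return stat >= observed if alternative == "greater" else stat <= observed

    n = labels.size
    n1 = int((class_idx == 1).sum())
    if exhaustive:
        hits = np.zeros_like(observed)
        total = 0
        template = np.empty(n, dtype=labels.dtype)
        for pos in combinations(range(n), n1):
            template[:] = classes[0]
            template[list(pos)] = classes[1]
            stat = np.atleast_1d(np.asarray(stat_fn(template.copy()), dtype=float))
            hits += extreme(stat)
            total += 1
        p = hits / total
    else:
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        hits = np.zeros_like(observed)
        for _ in range(n_perm):
            shuffled = rng.permutation(labels)
            stat = np.atleast_1d(np.asarray(stat_fn(shuffled), dtype=float))
            hits += extreme(stat)
        p = (1.0 + hits) / (1.0 + n_perm)
    return float(p[0]) if p.size == 1 and np.isscalar(observed_stat) else p
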
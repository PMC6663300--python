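"""Hierarchical statistical tests for greedy network inference.

The greedy selection performs one comparison per remaining candidate at
every iteration; the *maximum statistic* test controls the family-wise
error rate over those comparisons by comparing the best observed CMI
against the null distribution of the maximum surrogate CMI across all
candidates.  The *minimum statistic* test is its mirror image, used while
pruning.  The *omnibus* test assesses the collective transfer entropy of
the whole selected source set, and its p-value feeds a network-level
Benjamini-Hochberg FDR correction across targets.

Null distributions are either empirical (surrogate permutations) or, for
the Gaussian estimator, analytic: under conditional independence each
candidate's estimate has CDF F given by the chi-squared result, and with
the candidates' null estimates treated as i.i.d. the maximum has CDF F^n.

p-value convention: the fraction of surrogate extreme statistics strictly
larger than the observed statistic (for both the maximum and the minimum
test), so p = 0 is attainable; the ``S > 1/alpha`` configuration rule
guards the resolution of the empirical null.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "NullDistribution",
    "max_statistic_test",
    "min_statistic_test",
    "omnibus_test",
    "vfpr_from_alpha",
    "tfpr_from_alpha",
    "fdr_combine_targets",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of one significance test (statistic in nats)."""

    statistic: float
    p_value: float
    alpha: float

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass(frozen=True)
class NullDistribution:
    """Empirical null: one extreme statistic per surrogate."""

    values: np.ndarray
    n_candidates: int

    @property
    def n_surrogates(self) -> int:
        return len(self.values)


def _check_alpha(alpha: float) -> None:
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")


def max_statistic_test(
    observed: Sequence[float],
    alpha: float,
    surrogate_stats: np.ndarray | None = None,
    null_cdf: Callable[[float], float] | None = None,
) -> tuple[TestResult, NullDistribution | None]:
    """Test the largest candidate CMI against the null of the maximum.

    Parameters
    ----------
    observed
        CMI estimate for each of the n remaining candidates.
    surrogate_stats
        (n, S) matrix of surrogate CMI values, one row per candidate; the
        null distribution is the per-surrogate maximum over candidates and
        the p-value is the fraction of those maxima strictly larger than
        the observed maximum.
    null_cdf
        Analytic single-variable null CDF F; replaces the surrogate loop
        with p = 1 - F(max)^n.

    Exactly one of ``surrogate_stats`` / ``null_cdf`` must be given.
    """
    _check_alpha(alpha)
    observed = np.asarray(observed, dtype=float)
    if observed.size == 0:
        raise ValueError("empty candidate set: stop the iteration instead")
    statistic = float(observed.max())
    if (surrogate_stats is None) == (null_cdf is None):
        raise ValueError("provide exactly one of surrogate_stats or null_cdf")
    if null_cdf is not None:
        p = 1.0 - null_cdf(statistic) ** observed.size
        return TestResult(statistic, float(p), alpha), None
    surrogate_stats = np.asarray(surrogate_stats, dtype=float)
    if surrogate_stats.shape[0] != observed.size:
        raise ValueError("one surrogate row per candidate required")
    null = surrogate_stats.max(axis=0)
    p = float(np.mean(null > statistic))
    return TestResult(statistic, p, alpha), NullDistribution(null, observed.size)


def min_statistic_test(
    observed: Sequence[float],
    alpha: float,
    surrogate_stats: np.ndarray | None = None,
    null_cdf: Callable[[float], float] | None = None,
) -> tuple[TestResult, NullDistribution | None]:
    """Test the smallest selected-variable CMI against the null of the minimum.

    Identical in structure to :func:`max_statistic_test` with the minimum
    in place of the maximum: the null distribution collects per-surrogate
    minima, and the p-value is the fraction of those minima strictly
    larger than the observed minimum.  A significant result means even the
    weakest selected variable contributes beyond chance; a non-significant
    one marks it redundant.  The analytic form uses
    P(min > value) = (1 - F(value))^n.
    """
    _check_alpha(alpha)
    observed = np.asarray(observed, dtype=float)
    if observed.size == 0:
        raise ValueError("empty selected set: nothing to prune")
    statistic = float(observed.min())
    if (surrogate_stats is None) == (null_cdf is None):
        raise ValueError("provide exactly one of surrogate_stats or null_cdf")
    if null_cdf is not None:
        p = (1.0 - null_cdf(statistic)) ** observed.size
        return TestResult(statistic, float(p), alpha), None
    surrogate_stats = np.asarray(surrogate_stats, dtype=float)
    if surrogate_stats.shape[0] != observed.size:
        raise ValueError("one surrogate row per selected variable required")
    null = surrogate_stats.min(axis=0)
    p = float(np.mean(null > statistic))
    return TestResult(statistic, p, alpha), NullDistribution(null, observed.size)


def omnibus_test(
    statistic: float,
    alpha: float,
    surrogate_stats: np.ndarray | None = None,
    null_cdf: Callable[[float], float] | None = None,
) -> tuple[TestResult, NullDistribution | None]:
    """Test the collective transfer entropy T* = I(sources; Y_t | target past).

    Surrogates permute the joint rows of all selected-source realizations
    together (the caller supplies the resulting statistics), leaving the
    target and its past intact; the p-value is the fraction of surrogate
    statistics strictly larger than T*.
    """
    _check_alpha(alpha)
    statistic = float(statistic)
    if (surrogate_stats is None) == (null_cdf is None):
        raise ValueError("provide exactly one of surrogate_stats or null_cdf")
    if null_cdf is not None:
        p = 1.0 - null_cdf(statistic)
        return TestResult(statistic, float(p), alpha), None
    null = np.asarray(surrogate_stats, dtype=float)
    p = float(np.mean(null > statistic))
    return TestResult(statistic, p, alpha), NullDistribution(null, 1)


def vfpr_from_alpha(alpha_max: float, n: int) -> float:
    """Per-variable false-positive rate implied by the maximum statistic test.

    ``vFPR = 1 - (1 - alpha_max)^(1/n)`` over n comparisons — the
    Dunn-Sidak relation; always at least the Bonferroni rate alpha/n.
    """
    _check_alpha(alpha_max)
    if n < 1:
        raise ValueError("n must be >= 1")
    return 1.0 - (1.0 - alpha_max) ** (1.0 / n)


def tfpr_from_alpha(alpha_max: float, n: int) -> float:
    """Per-target family-wise error rate over n step-down iterations.

    Sums the chance that the variable accepted at step j is a false
    positive, alpha^j, giving ``alpha (1 - alpha^n) / (1 - alpha)``;
    approximately alpha for the small levels used in practice.
    """
    _check_alpha(alpha_max)
    if n < 1:
        raise ValueError("n must be >= 1")
    return alpha_max * (1.0 - alpha_max**n) / (1.0 - alpha_max)


def fdr_combine_targets(p_values: Sequence[float], q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up over per-target omnibus p-values.

    Returns a boolean keep-mask; a rejected target loses all its inferred
    links.  Decisions do not depend on the order of the targets.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0.0 < q < 1.0:
        raise ValueError(f"q must be in (0, 1), got {q}")
    return multipletests(p, alpha=q, method="fdr_bh")[0]
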
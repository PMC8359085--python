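"""Univariate between-group comparison machinery.

Continuous variables are screened per group for normality
(Kolmogorov-Smirnov against a normal with the sample mean and sd, without
the Lilliefors estimated-parameter correction) and then compared with an
independent-sample t test when both groups pass, otherwise with a
Mann-Whitney U test (exact enumeration for small untied samples, otherwise
the tie-corrected normal approximation). Categorical 2xk tables use the
chi-squared test without continuity correction, falling back to Fisher's
exact test for 2x2 tables with small expected counts. All probabilities are
two-tailed.

Rank means (the average pooled mid-rank per group) are always reported
alongside the group means and medians, matching the reporting format of
clinical texture-comparison tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "GroupComparison",
    "normality_test",
    "compare_groups_continuous",
    "compare_groups_categorical",
]

NORMALITY_ALPHA = 0.05


@dataclass(frozen=True)
class GroupComparison:
    """Outcome of one continuous between-group comparison."""

    feature: str
    rank_mean: tuple[float, float]
    mean: tuple[float, float]
    median: tuple[float, float]
    statistic: float
    statistic_kind: str  # "t" or "mannwhitney"
    p: float


def normality_test(values: np.ndarray) -> float:
    """One-sample Kolmogorov-Smirnov p against N(sample mean, sample sd).

    A constant sample has no distribution to test; it is reported maximally
    non-normal (p = 0) with a warning.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 5:
        raise ValueError("normality test needs n >= 5")
    sd = x.std(ddof=1)
    if sd == 0:
        warnings.warn("constant sample: reported as non-normal (p = 0)", stacklevel=2)
        return 0.0
    return float(stats.kstest(x, "norm", args=(x.mean(), sd)).pvalue)


def _rank_means(x0: np.ndarray, x1: np.ndarray) -> tuple[float, float]:
    pooled = np.concatenate([x0, x1])
    ranks = stats.rankdata(pooled)
    return float(ranks[: x0.size].mean()), float(ranks[x0.size :].mean())


def compare_groups_continuous(
    x0: np.ndarray,
    x1: np.ndarray,
    feature: str = "",
    force_test: str | None = None,
) -> GroupComparison:
    """Compare two independent samples, choosing the test "as appropriate".

    The t test (pooled variance) is used when both groups have n >= 5 and
    pass the KS normality screen at alpha = 0.05; otherwise Mann-Whitney.
    ``force_test`` ("t" or "mannwhitney") overrides the gate. Mann-Whitney
    uses exact enumeration when min(n0, n1) <= 10 and the pooled sample has
    no ties, else the tie-corrected normal approximation.
    """
    x0 = np.asarray(x0, dtype=float).ravel()
    x1 = np.asarray(x1, dtype=float).ravel()
    if x0.size < 2 or x1.size < 2:
        raise ValueError("each group needs n >= 2")
    if force_test not in (None, "t", "mannwhitney"):
        raise ValueError(f"unknown force_test {force_test!r}")

    kind = force_test
    if kind is None:
        both_normal = (
            x0.size >= 5
            and x1.size >= 5
            and x0.std(ddof=1) > 0
            and x1.std(ddof=1) > 0
            and normality_test(x0) > NORMALITY_ALPHA
            and normality_test(x1) > NORMALITY_ALPHA
        )
        kind = "t" if both_normal else "mannwhitney"

    rank0, rank1 = _rank_means(x0, x1)
    if kind == "t":
        res = stats.ttest_ind(x0, x1, equal_var=True)
        statistic, p = float(res.statistic), float(res.pvalue)
    else:
        pooled = np.concatenate([x0, x1])
        has_ties = np.unique(pooled).size < pooled.size
        small = min(x0.size, x1.size) <= 10
        method = "exact" if (small and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(x0, x1, alternative="two-sided", method=method)
        statistic, p = float(res.statistic), float(res.pvalue)
    return GroupComparison(
        feature=feature,
        rank_mean=(rank0, rank1),
        mean=(float(x0.mean()), float(x1.mean())),
        median=(float(np.median(x0)), float(np.median(x1))),
        statistic=statistic,
        statistic_kind=kind,
        p=min(1.0, p),
    )


def compare_groups_categorical(counts: np.ndarray) -> tuple[str, float]:
    """Compare a 2xk contingency table; returns (test kind, two-tailed p).

    Chi-squared without continuity correction when all expected counts are
    >= 5; Fisher's exact test otherwise (2x2 only — wider tables with small
    expecteds fall back to chi-squared with a warning).
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[0] != 2:
        raise ValueError("expected a 2xk contingency table")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=1) <= 0).any() or (table.sum(axis=0) <= 0).any():
        raise ValueError("both margins must be positive")

    expected = stats.contingency.expected_freq(table)
    if (expected >= 5).all():
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        return "chi2", float(min(1.0, p))
    if table.shape[1] == 2:
        _, p = stats.fisher_exact(table, alternative="two-sided")
        return "fisher", float(min(1.0, p))
    warnings.warn(
        "small expected counts in a 2xk table with k > 2: Fisher's exact "
        "test is restricted to 2x2, using chi-squared",
        stacklevel=2,
    )
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return "chi2", float(min(1.0, p))
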
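"""Statistical toolbox used across the analyses.

D'Agostino's K² omnibus normality test, two-sample comparisons (paired or
unpaired t tests) with Bonferroni adjustment, one-way ANOVA with Tukey's
HSD post hoc for multi-condition datasets, and the normal-approximation
sample-size calculation for comparing two means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "PowerSpec",
    "TestResult",
    "normality_k2",
    "compare_groups",
    "sample_size_two_means",
]


@dataclass(frozen=True)
class PowerSpec:
    """Design parameters for a two-mean sample-size calculation."""

    mu1: float
    mu2: float
    sigma: float  # common SD of the measured quantity
    alpha: float = 0.05  # two-sided type-I error rate
    power: float = 0.8
    ratio: float = 1.0  # allocation n2/n1

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not (0 < self.alpha < 1) or not (0 < self.power < 1):
            raise ValueError("alpha and power must lie in (0, 1)")
        if self.ratio <= 0:
            raise ValueError("ratio must be positive")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    raw_p: float
    adjusted_p: float
    method: str
    n: tuple[int, ...]
    comparison: str = ""


def normality_k2(sample: np.ndarray) -> TestResult:
    """D'Agostino's K² omnibus test of Gaussian normality.

    Combines the standardized skewness and kurtosis scores into a
    statistic referred to a chi-square distribution with 2 df.  Requires
    at least 8 observations and nonzero variance.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 8:
        raise ValueError("K² test requires at least 8 observations")
    if x.std() == 0:
        raise ValueError("zero-variance sample")
    k2, p = sps.normaltest(x)
    return TestResult(float(k2), float(p), float(p), "dagostino_k2", (x.size,))


def bonferroni(p: float, n_comparisons: int) -> float:
    return min(1.0, p * n_comparisons)


def compare_groups(
    samples: list[np.ndarray],
    paired: bool = False,
    n_comparisons: int = 1,
) -> list[TestResult]:
    """Compare condition groups the way the analyses report them.

    Two groups: Student's t test (paired or unpaired) with Bonferroni-
    adjusted p = min(1, raw_p * n_comparisons).  More than two groups:
    one-way ANOVA, followed by Tukey's multiple-comparison test for every
    pair.  Returns a list of TestResult (the ANOVA result first when
    applicable).
    """
    groups = [np.asarray(g, dtype=float) for g in samples]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if len(groups) == 2:
        a, b = groups
        if paired:
            if a.size != b.size:
                raise ValueError("paired comparison requires equal group sizes")
            t, p = sps.ttest_rel(a, b)
            method = "paired_t"
        else:
            t, p = sps.ttest_ind(a, b)
            method = "unpaired_t"
        return [
            TestResult(
                float(t), float(p), bonferroni(float(p), n_comparisons),
                method, (a.size, b.size), "group0 vs group1",
            )
        ]
    f, p = sps.f_oneway(*groups)
    out = [
        TestResult(
            float(f), float(p), bonferroni(float(p), n_comparisons),
            "one_way_anova", tuple(g.size for g in groups), "omnibus",
        )
    ]
    values = np.concatenate(groups)
    labels = np.concatenate([[f"g{i}"] for i, g in enumerate(groups) for _ in range(g.size)])
    tk = pairwise_tukeyhsd(values, labels)
    for (g1, g2, meandiff, p_adj, *_rest) in tk.summary().data[1:]:
        out.append(
            TestResult(
                float(meandiff), float(p_adj), float(p_adj), "tukey_hsd",
                tuple(g.size for g in groups), f"{g1} vs {g2}",
            )
        )
    return out


def sample_size_two_means(spec: PowerSpec) -> int:
    """Smallest per-group n for a two-sided two-sample comparison of means.

    Normal-approximation formula:
        n1 = (z_{1-alpha/2} + z_{power})² * sigma² * (1 + 1/ratio) / delta²
    rounded up, with n2 = ratio * n1 and delta = mu1 - mu2; the floor is
    one observation per group.
    """
    delta = spec.mu1 - spec.mu2
    if delta == 0:
        raise ValueError("mu1 and mu2 must differ")
    z_a = sps.norm.ppf(1 - spec.alpha / 2)
    z_b = sps.norm.ppf(spec.power)
    n1 = (z_a + z_b) ** 2 * spec.sigma**2 * (1 + 1 / spec.ratio) / delta**2
    return max(1, math.ceil(n1))
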
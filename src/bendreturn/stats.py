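"""Group comparison and measurement-difference statistics.

Two-group comparisons follow the classical decision rule: Shapiro-Wilk
normality on each group at alpha = 0.05; if both pass, a two-sided two-sample
t-test with mean/SD/SEM descriptives, otherwise a Mann-Whitney rank-sum test
with median/quartile descriptives.

For a between-group difference with per-group sample size N and standard
deviation SD, the reliability-style derived quantities are

    SEM = SD / sqrt(N)          (standard error of measurement)
    CI  = 1.96 * SEM            (95% confidence half-width)
    MDC = 1.96 * sqrt(2) * SEM  (minimal detectable change)

so MDC = sqrt(2) * CI identically.  The z-multiplier 1.96 is used rather
than a t-quantile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["GroupComparison", "DiffStats", "compare_groups", "difference_metrics"]


@dataclass(frozen=True)
class GroupComparison:
    """Result of a two-group location comparison."""

    test: str                      # "t" or "mann-whitney"
    p_value: float
    normality_p: tuple[float, float]
    # Descriptives in the style matching the chosen test:
    # t-test -> (mean, SD, SEM) per group; rank test -> (median, Q1, Q3).
    descriptives_a: dict[str, float]
    descriptives_b: dict[str, float]
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def _parametric_desc(x: np.ndarray) -> dict[str, float]:
    return {
        "mean": float(x.mean()),
        "SD": float(x.std(ddof=1)),
        "SEM": float(x.std(ddof=1) / math.sqrt(x.size)),
    }


def _rank_desc(x: np.ndarray) -> dict[str, float]:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return {"median": float(med), "Q1": float(q1), "Q3": float(q3)}


def compare_groups(
    a: np.ndarray, b: np.ndarray, alpha: float = 0.05
) -> GroupComparison:
    """Compare two groups of values with the normality-gated test choice."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size < 3 or b.size < 3:
        raise ValueError(
            f"need >= 3 values per group, got {a.size} and {b.size}"
        )
    pa = float(sps.shapiro(a).pvalue)
    pb = float(sps.shapiro(b).pvalue)
    if pa >= alpha and pb >= alpha:
        p = float(sps.ttest_ind(a, b).pvalue)
        return GroupComparison(
            test="t", p_value=p, normality_p=(pa, pb),
            descriptives_a=_parametric_desc(a), descriptives_b=_parametric_desc(b),
            alpha=alpha,
        )
    p = float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return GroupComparison(
        test="mann-whitney", p_value=p, normality_p=(pa, pb),
        descriptives_a=_rank_desc(a), descriptives_b=_rank_desc(b),
        alpha=alpha,
    )


@dataclass(frozen=True)
class DiffStats:
    """SEM / CI / MDC for a group difference of given SD and sample size."""

    sd_diff: float
    n: int
    sem: float
    ci: float
    mdc: float

    def rounded(self, ndigits: int = 3) -> "DiffStats":
        return DiffStats(
            sd_diff=self.sd_diff, n=self.n,
            sem=round(self.sem, ndigits),
            ci=round(self.ci, ndigits),
            mdc=round(self.mdc, ndigits),
        )


def difference_metrics(sd_diff: float, n: int) -> DiffStats:
    """SEM, 95% CI half-width and MDC for a difference with SD *sd_diff*."""
    if n < 2:
        raise ValueError(f"need n >= 2, got {n}")
    if sd_diff < 0:
        raise ValueError(f"sd_diff must be >= 0, got {sd_diff}")
    sem = sd_diff / math.sqrt(n)
    return DiffStats(
        sd_diff=sd_diff, n=n,
        sem=sem, ci=1.96 * sem, mdc=1.96 * math.sqrt(2.0) * sem,
    )
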
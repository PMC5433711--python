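"""The four two-sample tests and the assumption-driven selection rule.

The selection table, applied independently to every unordered pair of
groups:

=============  =================  ==================
normality      variances similar  variances dissimilar
=============  =================  ==================
both normal    Student t          Welch t
any non-normal Mann-Whitney U     Welch U (rank Welch)
=============  =================  ==================

"Welch's U" is Welch's unequal-variance t-test applied to the midranks of
the pooled pair — a rank-transform answer to the nonparametric
Behrens-Fisher problem.  Ranks are assigned over the two samples of the
pair only, matching the per-combination testing frame.  All p-values are
two-sided.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import AnalysisConfig, GroupData
from .assumptions import NormalityVerdict, VarianceResult
from .exceptions import DegenerateDataError, SampleSizeError

__all__ = [
    "TestName",
    "PairTestResult",
    "student_t",
    "welch_t",
    "mann_whitney_u",
    "welch_u",
    "select_and_run",
]


class TestName(str, enum.Enum):
    __test__ = False  # not a pytest class despite the name

    STUDENT_T = "student_t"
    WELCH_T = "welch_t"
    MANN_WHITNEY_U = "mann_whitney_u"
    WELCH_U = "welch_u"


@dataclass(frozen=True)
class PairTestResult:
    test_name: TestName
    statistic: float
    p: float
    df: float | None = None
    method_detail: str = ""


def _as_samples(a, b, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    xa = np.asarray(a, dtype=float).ravel()
    xb = np.asarray(b, dtype=float).ravel()
    if xa.size < min_n or xb.size < min_n:
        raise SampleSizeError(f"each sample needs at least {min_n} observations")
    return xa, xb


def student_t(a, b) -> PairTestResult:
    """Pooled-variance two-sided t-test, df = n1 + n2 - 2."""
    xa, xb = _as_samples(a, b, 2)
    if xa.var(ddof=1) == 0.0 and xb.var(ddof=1) == 0.0:
        raise DegenerateDataError("pooled variance is zero")
    res = stats.ttest_ind(xa, xb, equal_var=True)
    return PairTestResult(TestName.STUDENT_T, float(res.statistic), float(res.pvalue),
                          df=float(xa.size + xb.size - 2), method_detail="pooled variance")


def welch_t(a, b) -> PairTestResult:
    """Unpooled two-sided t-test with Welch-Satterthwaite df."""
    xa, xb = _as_samples(a, b, 2)
    if xa.var(ddof=1) == 0.0 or xb.var(ddof=1) == 0.0:
        raise DegenerateDataError("zero variance in a sample; Welch df undefined")
    res = stats.ttest_ind(xa, xb, equal_var=False)
    return PairTestResult(TestName.WELCH_T, float(res.statistic), float(res.pvalue),
                          df=float(res.df), method_detail="Welch-Satterthwaite df")


def mann_whitney_u(a, b, cfg: AnalysisConfig | None = None) -> PairTestResult:
    """Two-sided Mann-Whitney U.

    Exact enumeration when the combined sample size is at most
    ``cfg.exact_mw_threshold`` and there are no ties; otherwise the
    normal approximation with tie and continuity corrections.
    """
    cfg = cfg or AnalysisConfig()
    xa, xb = _as_samples(a, b, 1)
    pooled = np.concatenate([xa, xb])
    ties = np.unique(pooled).size < pooled.size
    exact = (pooled.size <= cfg.exact_mw_threshold) and not ties
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(xa, xb, alternative="two-sided", method=method,
                             use_continuity=True)
    detail = "exact enumeration" if exact else (
        "normal approximation, tie + continuity correction" if ties
        else "normal approximation, continuity correction")
    return PairTestResult(TestName.MANN_WHITNEY_U, float(res.statistic),
                          float(min(res.pvalue, 1.0)), df=None, method_detail=detail)


def welch_u(a, b) -> PairTestResult:
    """Welch's t-test on the midranks of the pooled pair ("Welch's U").

    Ties receive the average of the ranks they straddle.  A sample whose
    ranks are all tied has zero rank variance and is degenerate.
    """
    xa, xb = _as_samples(a, b, 2)
    pooled = np.concatenate([xa, xb])
    if np.ptp(pooled) == 0.0:
        raise DegenerateDataError("all pooled values identical; ranks carry no information")
    ranks = stats.rankdata(pooled, method="average")
    ra, rb = ranks[: xa.size], ranks[xa.size:]
    if ra.var(ddof=1) == 0.0 or rb.var(ddof=1) == 0.0:
        raise DegenerateDataError("a sample's ranks are all tied; Welch on ranks undefined")
    res = stats.ttest_ind(ra, rb, equal_var=False)
    return PairTestResult(TestName.WELCH_U, float(res.statistic), float(res.pvalue),
                          df=float(res.df), method_detail="Welch t on pooled midranks")


def select_and_run(
    a: GroupData,
    b: GroupData,
    verdict_a: NormalityVerdict,
    verdict_b: NormalityVerdict,
    variance: VarianceResult,
    cfg: AnalysisConfig | None = None,
) -> PairTestResult:
    """Apply the selection table and run the chosen test.

    Both-normal pairs get Student's t (similar variances) or Welch's t
    (dissimilar); pairs with any non-normal member get Mann-Whitney U
    (similar) or Welch's U (dissimilar).
    """
    cfg = cfg or AnalysisConfig()
    both_normal = verdict_a.is_normal and verdict_b.is_normal
    if both_normal:
        if variance.similar_variance:
            return student_t(a.values, b.values)
        return welch_t(a.values, b.values)
    if variance.similar_variance:
        return mann_whitney_u(a.values, b.values, cfg)
    return welch_u(a.values, b.values)
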
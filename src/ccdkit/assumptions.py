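"""Normality battery and variance-homogeneity pretests.

Every sample (one group, one endpoint) is screened with three normality
tests — Shapiro-Wilk, Anderson-Darling and a Kolmogorov-Smirnov test
against a normal with parameters estimated from the sample — plus two
graphical diagnostics (QQ plot, histogram with fitted normal overlay,
rendered by :mod:`ccdkit.figure`).  Each pair of samples is screened with
Levene's test for equal variances.  The verdicts feed the two-sample test
selection in :mod:`ccdkit.pairwise`.

Because the normal's mean and sd are estimated from the same data, the
plain KS null distribution is badly conservative; we therefore use the
Lilliefors-corrected null by default and keep the uncorrected p available
for comparison.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors, normal_ad

from .data import AnalysisConfig, NormalityRule, StudyDataset
from .exceptions import DegenerateDataError, SampleSizeError

__all__ = [
    "NormalityTest",
    "NormalityResult",
    "NormalityVerdict",
    "VarianceResult",
    "shapiro_wilk",
    "anderson_darling",
    "kolmogorov_smirnov",
    "classify_normality",
    "qq_points",
    "levene",
    "normality_report",
]


class NormalityTest(str, enum.Enum):
    SHAPIRO_WILK = "shapiro_wilk"
    ANDERSON_DARLING = "anderson_darling"
    KOLMOGOROV_SMIRNOV = "kolmogorov_smirnov"


@dataclass(frozen=True)
class NormalityResult:
    test: NormalityTest
    statistic: float
    p: float
    reject: bool


@dataclass(frozen=True)
class NormalityVerdict:
    results: tuple[NormalityResult, ...]
    is_normal: bool
    rule_used: NormalityRule
    errors: tuple[str, ...] = ()

    def result(self, test: NormalityTest) -> NormalityResult:
        for r in self.results:
            if r.test is test:
                return r
        raise KeyError(test)


@dataclass(frozen=True)
class VarianceResult:
    statistic: float
    p: float
    similar_variance: bool


def _check_sample(values, min_n: int) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    if x.size < min_n:
        raise SampleSizeError(f"need at least {min_n} observations, got {x.size}")
    if np.ptp(x) == 0.0:
        raise DegenerateDataError("all observations identical; normality undefined")
    return x


def shapiro_wilk(values, alpha: float = 0.05) -> NormalityResult:
    """Shapiro-Wilk W test (n >= 3)."""
    x = _check_sample(values, 3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # small-sample p-value accuracy notes
        stat, p = stats.shapiro(x)
    return NormalityResult(NormalityTest.SHAPIRO_WILK, float(stat), float(p),
                           reject=bool(p <= alpha))


def anderson_darling(values, alpha: float = 0.05) -> NormalityResult:
    """Anderson-Darling A² with estimated mean/sd and a continuous p-value."""
    x = _check_sample(values, 3)
    stat, p = normal_ad(x)
    return NormalityResult(NormalityTest.ANDERSON_DARLING, float(stat),
                           float(min(p, 1.0)), reject=bool(p <= alpha))


def kolmogorov_smirnov(values, alpha: float = 0.05, corrected: bool = True) -> NormalityResult:
    """One-sample KS distance against N(mean, sd) estimated from the sample.

    With ``corrected=True`` (default) the p-value comes from the
    Lilliefors null distribution, which accounts for the estimated
    parameters; the uncorrected variant plugs the estimates into the
    standard KS null and is strongly conservative.
    """
    x = _check_sample(values, 4)
    if corrected:
        stat, p = lilliefors(x, dist="norm", pvalmethod="table")
    else:
        stat, p = stats.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    return NormalityResult(NormalityTest.KOLMOGOROV_SMIRNOV, float(stat),
                           float(min(p, 1.0)), reject=bool(p <= alpha))


_BATTERY = (shapiro_wilk, anderson_darling, kolmogorov_smirnov)


def classify_normality(values, cfg: AnalysisConfig | None = None) -> NormalityVerdict:
    """Run the three-test battery and aggregate the reject flags.

    Aggregation rules: ``any`` (default) calls the sample non-normal if
    any single test rejects; ``majority`` requires at least two
    rejections; ``all`` requires all three.  If one test fails on an
    otherwise valid sample, the verdict proceeds on the remaining tests
    (at least two are required).
    """
    cfg = cfg or AnalysisConfig()
    results: list[NormalityResult] = []
    errors: list[str] = []
    for fn in _BATTERY:
        try:
            results.append(fn(values, alpha=cfg.alpha))
        except (SampleSizeError, DegenerateDataError) as exc:
            errors.append(f"{fn.__name__}: {exc}")
    if len(results) < 2:
        raise SampleSizeError(
            "normality battery needs at least two usable tests; " + "; ".join(errors)
        )
    rejections = sum(r.reject for r in results)
    rule = cfg.normality_rule
    if rule is NormalityRule.ANY:
        non_normal = rejections >= 1
    elif rule is NormalityRule.MAJORITY:
        non_normal = rejections > len(results) / 2
    else:
        non_normal = rejections == len(results)
    return NormalityVerdict(tuple(results), is_normal=not non_normal,
                            rule_used=rule, errors=tuple(errors))


def qq_points(values) -> np.ndarray:
    """Standard-normal QQ coordinates at plotting positions (i - 0.5)/n.

    Returns an (n, 2) array of (theoretical quantile, ordered value)
    pairs, sorted ascending.
    """
    x = np.sort(np.asarray(values, dtype=float))
    if x.size < 3:
        raise SampleSizeError("QQ plot needs at least 3 observations")
    probs = (np.arange(1, x.size + 1) - 0.5) / x.size
    return np.column_stack([stats.norm.ppf(probs), x])


def levene(a, b, cfg: AnalysisConfig | None = None) -> VarianceResult:
    """Two-group Levene test for equal variances (mean centering).

    ``similar_variance`` is true when p exceeds alpha.  Median centering
    (Brown-Forsythe) is available through ``cfg.levene_center``.
    """
    cfg = cfg or AnalysisConfig()
    xa = np.asarray(a, dtype=float)
    xb = np.asarray(b, dtype=float)
    if xa.size < 2 or xb.size < 2:
        raise SampleSizeError("Levene's test needs at least 2 observations per group")
    if np.ptp(xa) == 0.0 and np.ptp(xb) == 0.0:
        raise DegenerateDataError("both samples constant; variance ratio undefined")
    if np.array_equal(xa, xb):
        # identical lists: absolute deviations coincide exactly; scipy
        # returns W=0 with a NaN/1 p depending on version, so pin it
        return VarianceResult(0.0, 1.0, True)
    stat, p = stats.levene(xa, xb, center=cfg.levene_center)
    return VarianceResult(float(stat), float(p), similar_variance=bool(p > cfg.alpha))


def normality_report(dataset: StudyDataset, cfg: AnalysisConfig | None = None) -> pd.DataFrame:
    """Tidy per-group normality table: group x test x statistic x p x verdict."""
    cfg = cfg or AnalysisConfig()
    rows = []
    for g in dataset.groups:
        verdict = classify_normality(g.values, cfg)
        for r in verdict.results:
            rows.append({
                "group": g.label,
                "test": r.test.value,
                "statistic": r.statistic,
                "p": r.p,
                "reject": r.reject,
                "is_normal": verdict.is_normal,
                "rule": verdict.rule_used.value,
            })
    return pd.DataFrame(rows)
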
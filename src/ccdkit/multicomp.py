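"""Family-adjusted p-values and assembly of the complete comparison matrix.

Every branch of the staircase display carries three p-values, top to
bottom:

1. the adaptively selected two-sample test for the pair (or always the
   pooled Student t in strict display mode),
2. Tukey's honest significant difference over all groups (Tukey-Kramer
   standard error when group sizes differ),
3. Dunnett's two-tailed many-to-one adjustment.

Dunnett needs a designated control, which the staircase layout supplies
naturally: the tier anchored at group *g* compares *g* against every
group displayed after it, so that tier is one Dunnett family with *g* as
control.  Under this reading every one of the K(K-1)/2 branches has a
well-defined Dunnett value.

The Dunnett adjusted p-value is the equicoordinate probability
``P(max_j |T_j| >= |t_i|)`` under a central multivariate t whose
correlation comes from the shared control group.  We evaluate it by
Monte-Carlo, conditioning on the control-group variate and the pooled
variance estimate so that only smooth normal-CDF products are averaged
(a large variance reduction over raw max-|t| sampling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import AnalysisConfig, StudyDataset
from .assumptions import classify_normality, levene
from .pairwise import PairTestResult, select_and_run, student_t
from .exceptions import DegenerateDataError, NotFoundError, SampleSizeError, ValidationError

__all__ = [
    "PairwiseComparison",
    "ComparisonMatrix",
    "tukey_hsd",
    "dunnett_two_tailed",
    "build_matrix",
]


@dataclass(frozen=True)
class PairwiseComparison:
    """One unordered pair of groups with its three p-values."""

    group_a: str
    group_b: str
    selected: PairTestResult | None
    p_tukey: float
    p_dunnett: float
    tukey_significant: bool
    error: str | None = None


@dataclass(frozen=True)
class ComparisonMatrix:
    """All C(K,2) pairwise comparisons for one endpoint, in tier order."""

    endpoint: str
    labels: tuple[str, ...]
    comparisons: tuple[PairwiseComparison, ...]
    config: AnalysisConfig
    seed: int

    def pair(self, a: str, b: str) -> PairwiseComparison:
        for c in self.comparisons:
            if {c.group_a, c.group_b} == {a, b}:
                return c
        raise NotFoundError(f"no comparison for pair ({a!r}, {b!r})")

    def to_frame(self) -> pd.DataFrame:
        """Delimited-table view of the matrix (one row per branch)."""
        rows = []
        for c in self.comparisons:
            rows.append({
                "group_a": c.group_a,
                "group_b": c.group_b,
                "test_name": c.selected.test_name.value if c.selected else "",
                "statistic": c.selected.statistic if c.selected else np.nan,
                "p_selected": c.selected.p if c.selected else np.nan,
                "p_tukey": c.p_tukey,
                "p_dunnett": c.p_dunnett,
                "tukey_significant": c.tukey_significant,
                "error": c.error or "",
            })
        return pd.DataFrame(rows)


def tukey_hsd(dataset: StudyDataset) -> dict[frozenset[str], float]:
    """Tukey HSD adjusted p for every unordered pair of groups.

    Uses the studentized-range distribution with the pooled within-group
    variance (df = N - K); unequal group sizes get the Tukey-Kramer
    standard error.
    """
    samples = [g.as_array() for g in dataset.groups]
    if any(s.size < 2 for s in samples):
        raise SampleSizeError("Tukey HSD needs at least 2 observations per group")
    if all(s.var(ddof=1) == 0.0 for s in samples):
        raise DegenerateDataError("zero within-group variance in every group")
    res = stats.tukey_hsd(*samples)
    out: dict[frozenset[str], float] = {}
    labels = dataset.labels
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            out[frozenset((labels[i], labels[j]))] = float(min(res.pvalue[i, j], 1.0))
    return out


def _dunnett_mc_p(
    q: np.ndarray, lambdas: np.ndarray, df: float, mc_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """P(max_j |T_j| >= q_i) for a central Dunnett multivariate t.

    T_j = (lam_j Z0 + sqrt(1-lam_j^2) X_j) / S with S^2 = chi2_df / df and
    Z0 shared across comparisons.  Conditioning on (Z0, S) leaves a
    product of normal-CDF differences, which we average over draws.
    """
    z0 = rng.standard_normal(mc_draws)
    s = np.sqrt(rng.chisquare(df, mc_draws) / df)
    tau = np.sqrt(1.0 - lambdas**2)
    out = np.empty(q.size)
    for i, qi in enumerate(q):
        hi = (qi * s[:, None] - lambdas * z0[:, None]) / tau
        lo = (-qi * s[:, None] - lambdas * z0[:, None]) / tau
        inside = np.prod(stats.norm.cdf(hi) - stats.norm.cdf(lo), axis=1)
        out[i] = 1.0 - inside.mean()
    return np.clip(out, 0.0, 1.0)


def dunnett_two_tailed(
    dataset: StudyDataset, control: str, cfg: AnalysisConfig | None = None,
    seed: int | None = None,
) -> dict[str, float]:
    """Two-tailed Dunnett-adjusted p for each non-control group vs control.

    The pooled within-family variance (df = N - K over the groups of
    ``dataset``) standardises each mean difference; adjusted p-values are
    equicoordinate multivariate-t tail probabilities, Monte-Carlo
    evaluated with ``cfg.mc_draws`` draws.  A single-treatment family
    reduces exactly to the pooled two-sample t-test and is computed in
    closed form.
    """
    cfg = cfg or AnalysisConfig()
    ctrl = dataset.group(control)  # raises NotFoundError for unknown labels
    treatments = [g for g in dataset.groups if g.label != control]
    if not treatments:
        raise ValidationError("Dunnett needs at least one non-control group")
    samples = [ctrl.as_array()] + [g.as_array() for g in treatments]
    ns = np.array([s.size for s in samples])
    if (ns < 2).any():
        raise SampleSizeError("Dunnett needs at least 2 observations per group")
    df = float(ns.sum() - len(samples))
    mse = sum(((s - s.mean()) ** 2).sum() for s in samples) / df
    if mse == 0.0:
        raise DegenerateDataError("zero pooled within-group variance")
    means = np.array([s.mean() for s in samples])
    se = np.sqrt(mse * (1.0 / ns[1:] + 1.0 / ns[0]))
    t = (means[1:] - means[0]) / se

    if len(treatments) == 1:
        p = np.array([2.0 * stats.t.sf(abs(t[0]), df)])
    else:
        lambdas = np.sqrt(ns[1:] / (ns[1:] + ns[0]))
        rng = np.random.default_rng(
            np.random.SeedSequence(cfg.seed if seed is None else seed))
        p = _dunnett_mc_p(np.abs(t), lambdas, df, cfg.mc_draws, rng)
    return {g.label: float(pi) for g, pi in zip(treatments, p)}


def build_matrix(dataset: StudyDataset, cfg: AnalysisConfig | None = None) -> ComparisonMatrix:
    """Assemble the full comparison matrix for one endpoint.

    For every unordered pair (in tier order: anchor group against each
    later group): the adaptively selected two-sample test, the all-group
    Tukey HSD p, and the Dunnett p from the tier family anchored at the
    earlier group.  Group-level degeneracies are recorded on the affected
    pairs instead of aborting the matrix.
    """
    cfg = cfg or AnalysisConfig()
    labels = dataset.labels
    k = len(labels)

    verdicts: dict[str, object] = {}
    verdict_errors: dict[str, str] = {}
    for g in dataset.groups:
        try:
            verdicts[g.label] = classify_normality(g.values, cfg)
        except (SampleSizeError, DegenerateDataError) as exc:
            verdict_errors[g.label] = str(exc)

    try:
        tukey = tukey_hsd(dataset)
        tukey_error = None
    except (SampleSizeError, DegenerateDataError) as exc:
        tukey, tukey_error = {}, str(exc)

    dunnett: dict[tuple[str, str], float] = {}
    dunnett_errors: dict[str, str] = {}
    for i in range(k - 1):
        tier = dataset.subset(labels[i:])
        try:
            for target, p in dunnett_two_tailed(
                    tier, labels[i], cfg, seed=_tier_seed(cfg.seed, i)).items():
                dunnett[(labels[i], target)] = p
        except (SampleSizeError, DegenerateDataError, ValidationError) as exc:
            dunnett_errors[labels[i]] = str(exc)

    comparisons: list[PairwiseComparison] = []
    for i in range(k - 1):
        for j in range(i + 1, k):
            a, b = dataset.groups[i], dataset.groups[j]
            errors: list[str] = []
            selected: PairTestResult | None = None
            try:
                if cfg.strict_student_t:
                    selected = student_t(a.values, b.values)
                else:
                    for lbl in (a.label, b.label):
                        if lbl in verdict_errors:
                            raise DegenerateDataError(
                                f"normality verdict unavailable for {lbl!r}: "
                                f"{verdict_errors[lbl]}")
                    var = levene(a.values, b.values, cfg)
                    selected = select_and_run(
                        a, b, verdicts[a.label], verdicts[b.label], var, cfg)
            except (SampleSizeError, DegenerateDataError) as exc:
                errors.append(f"selected test: {exc}")
            p_tukey = tukey.get(frozenset((a.label, b.label)), np.nan)
            if tukey_error:
                errors.append(f"tukey: {tukey_error}")
            p_dunnett = dunnett.get((a.label, b.label), np.nan)
            if (a.label, b.label) not in dunnett and a.label in dunnett_errors:
                errors.append(f"dunnett: {dunnett_errors[a.label]}")
            comparisons.append(PairwiseComparison(
                group_a=a.label,
                group_b=b.label,
                selected=selected,
                p_tukey=float(p_tukey),
                p_dunnett=float(p_dunnett),
                tukey_significant=bool(np.isfinite(p_tukey) and p_tukey <= cfg.alpha),
                error="; ".join(errors) or None,
            ))
    return ComparisonMatrix(endpoint=dataset.endpoint, labels=labels,
                            comparisons=tuple(comparisons), config=cfg, seed=cfg.seed)


def _tier_seed(seed: int, tier: int) -> int:
    """Deterministic per-tier Monte-Carlo seed derived from the base seed."""
    return int(np.random.SeedSequence(entropy=(seed, tier)).generate_state(1)[0] % (2**31))
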
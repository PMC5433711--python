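"""Synthetic factorial study generator and procedure-calibration harness.

Emulates the structure of an 8-arm lesion x extract rodent study: a
saline quartet and an MPTP (lesioned) quartet, each quartet holding an
untreated group and groups treated with Centella, Withania, or both
extracts.  Endpoints are either continuous (enzyme activities, latencies)
or ordinal (swim score 0-3, generated by cutting a latent continuous
variable at equally spaced thresholds).

Default effect sizes encode the qualitative pattern of such studies: a
large lesion deficit (about three within-group standard deviations),
partial single-extract recovery, and a non-additive combination whose
recovery does not exceed the better single extract.

The calibration harness replays the full pretest-then-test procedure on
replicate synthetic studies to measure its empirical size, power and
branch usage under controlled scenarios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .data import DEFAULT_DESIGN, AnalysisConfig, Extract, GroupData, StudyDataset
from .assumptions import classify_normality, levene
from .pairwise import TestName, select_and_run
from .exceptions import ValidationError

__all__ = [
    "SimulationConfig",
    "GROUP_ORDER",
    "generate_factorial_study",
    "simulate_procedure_calibration",
]

#: Canonical display order: saline quartet then MPTP quartet.
GROUP_ORDER: tuple[str, ...] = tuple(DEFAULT_DESIGN)

_NOISE_FAMILIES = ("normal", "lognormal", "contaminated_normal")


@dataclass(frozen=True)
class SimulationConfig:
    """Ground truth of one synthetic study.

    Group mean = ``baseline_mean`` + ``lesion_effect`` (lesioned groups)
    + the applicable recovery shift (lesioned, extract-treated) or
    unlesioned extract effect.  Noise is scaled by ``sd_per_group``
    (scalar, or one value per group in display order).
    """

    n_per_group: int = 6
    baseline_mean: float = 100.0
    lesion_effect: float = -30.0
    recovery_centella: float = 20.0
    recovery_withania: float = 15.0
    recovery_both: float = 15.0       # non-additive: no better than the best single
    extract_effect_unlesioned: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_family: str = "normal"
    sd_per_group: float | tuple[float, ...] = 10.0
    contamination_eps: float = 0.1
    contamination_scale: float = 5.0
    ordinal_levels: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValidationError("n_per_group must be at least 2")
        if self.noise_family not in _NOISE_FAMILIES:
            raise ValidationError(
                f"noise_family must be one of {_NOISE_FAMILIES}, got {self.noise_family!r}")
        sds = self.sds()
        if (sds <= 0).any():
            raise ValidationError("all sds must be positive")
        if not 0.0 <= self.contamination_eps < 1.0:
            raise ValidationError("contamination_eps must be in [0,1)")
        if self.ordinal_levels < 2:
            raise ValidationError("ordinal_levels must be at least 2")

    def sds(self) -> np.ndarray:
        sds = np.asarray(self.sd_per_group, dtype=float).ravel()
        if sds.size == 1:
            sds = np.repeat(sds, len(GROUP_ORDER))
        if sds.size != len(GROUP_ORDER):
            raise ValidationError(
                f"sd_per_group must be scalar or length {len(GROUP_ORDER)}")
        return sds

    def group_means(self) -> np.ndarray:
        """True cell means in display order."""
        recovery = {
            Extract.NONE: 0.0,
            Extract.CENTELLA: self.recovery_centella,
            Extract.WITHANIA: self.recovery_withania,
            Extract.BOTH: self.recovery_both,
        }
        unlesioned = {
            Extract.NONE: 0.0,
            Extract.CENTELLA: self.extract_effect_unlesioned[0],
            Extract.WITHANIA: self.extract_effect_unlesioned[1],
            Extract.BOTH: self.extract_effect_unlesioned[2],
        }
        means = []
        for label in GROUP_ORDER:
            lesion, extract = DEFAULT_DESIGN[label]
            mu = self.baseline_mean
            if lesion:
                mu += self.lesion_effect + recovery[extract]
            else:
                mu += unlesioned[extract]
            means.append(mu)
        return np.asarray(means)


def _noise(cfg: SimulationConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Zero-location noise draws with unit core scale, per noise family."""
    if cfg.noise_family == "normal":
        return rng.standard_normal(n)
    if cfg.noise_family == "lognormal":
        # standardised lognormal(0,1): zero mean, unit variance, right-skewed
        z = np.exp(rng.standard_normal(n))
        return (z - math.exp(0.5)) / math.sqrt((math.e - 1.0) * math.e)
    # contaminated normal: (1-eps) N(0,1) + eps N(0, scale^2)
    z = rng.standard_normal(n)
    widen = rng.random(n) < cfg.contamination_eps
    z[widen] *= cfg.contamination_scale
    return z


def generate_factorial_study(
    cfg: SimulationConfig,
    endpoint: str = "SOD",
    units: str = "",
    ordinal: bool = False,
    rng: np.random.Generator | None = None,
) -> StudyDataset:
    """Draw one synthetic 8-group study for a single endpoint.

    With ``ordinal=True`` the continuous draws act as a latent variable
    cut at ``ordinal_levels - 1`` equally spaced thresholds spanning the
    range of true cell means (plus one sd of head-room on each side),
    yielding scores in ``{0, ..., ordinal_levels - 1}``.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    means = cfg.group_means()
    sds = cfg.sds()
    groups = []
    latent: list[np.ndarray] = [
        means[i] + sds[i] * _noise(cfg, cfg.n_per_group, rng)
        for i in range(len(GROUP_ORDER))
    ]
    if ordinal:
        lo = means.min() - sds.max()
        hi = means.max() + sds.max()
        cuts = np.linspace(lo, hi, cfg.ordinal_levels + 1)[1:-1]
        latent = [np.searchsorted(cuts, x).astype(float) for x in latent]
    for i, label in enumerate(GROUP_ORDER):
        lesion, extract = DEFAULT_DESIGN[label]
        groups.append(GroupData(label=label, values=tuple(latent[i]),
                                lesion=lesion, extract=extract))
    return StudyDataset(endpoint=endpoint, groups=tuple(groups), units=units)


_SCENARIOS = ("null", "shift", "variance_shift", "heavy_tail")


def _scenario_config(cfg: SimulationConfig, scenario: str) -> SimulationConfig:
    """Scenario presets: overrides applied on top of the base config."""
    flat = dict(lesion_effect=0.0, recovery_centella=0.0, recovery_withania=0.0,
                recovery_both=0.0, extract_effect_unlesioned=(0.0, 0.0, 0.0))
    if scenario == "null":
        return replace(cfg, noise_family="normal", **flat)
    if scenario == "shift":
        return replace(cfg, noise_family="normal")
    if scenario == "variance_shift":
        sds = cfg.sds()
        lesioned = np.array([DEFAULT_DESIGN[l][0] for l in GROUP_ORDER])
        return replace(cfg, noise_family="normal",
                       sd_per_group=tuple(np.where(lesioned, 3.0 * sds, sds)), **flat)
    if scenario == "heavy_tail":
        return replace(cfg, noise_family="contaminated_normal", **flat)
    raise ValidationError(f"scenario must be one of {_SCENARIOS}, got {scenario!r}")


def simulate_procedure_calibration(
    cfg: SimulationConfig,
    reps: int,
    scenario: str = "null",
    analysis: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Replay the pretest-then-test procedure on replicate synthetic studies.

    For every replicate: run the three-test normality battery per group,
    Levene per pair, the selected two-sample test per pair, and Tukey HSD
    over all groups.  Returns a one-row table with

    - ``per_pair_rejection``: fraction of (pair, replicate) cells where
      the selected test rejected at alpha,
    - ``lesion_pair_rejection``: rejection rate for the untreated saline
      vs untreated lesioned pair (the design's primary contrast),
    - ``tukey_fwer``: fraction of replicates where any Tukey-adjusted p
      fell at or below alpha,
    - ``frac_<test>``: how often each of the four tests was chosen.
    """
    if reps < 1:
        raise ValidationError("reps must be positive")
    analysis = analysis or AnalysisConfig()
    scen_cfg = _scenario_config(cfg, scenario)
    k = len(GROUP_ORDER)
    rng = np.random.default_rng(np.random.SeedSequence(scen_cfg.seed))

    n_pairs = k * (k - 1) // 2
    rejections = 0
    cells = 0
    lesion_pair_rej = 0
    fwer_hits = 0
    usage = {t: 0 for t in TestName}
    i_ctrl = GROUP_ORDER.index("No Herbal Ext.")
    i_lesion = GROUP_ORDER.index("MPTP No Herbal Ext.")

    # Tukey family-wise hit <=> max studentized statistic exceeds the
    # alpha critical value; computing that critical value once avoids a
    # slow studentized-range CDF evaluation per pair per replicate.
    n = scen_cfg.n_per_group
    df_within = k * (n - 1)
    q_crit = stats.studentized_range.isf(analysis.alpha, k, df_within)
    iu = np.triu_indices(k, 1)

    for _ in range(reps):
        ds = generate_factorial_study(scen_cfg, rng=rng)
        verdicts = {g.label: classify_normality(g.values, analysis) for g in ds.groups}
        for i in range(k - 1):
            for j in range(i + 1, k):
                a, b = ds.groups[i], ds.groups[j]
                var = levene(a.values, b.values, analysis)
                res = select_and_run(a, b, verdicts[a.label], verdicts[b.label],
                                     var, analysis)
                usage[res.test_name] += 1
                cells += 1
                rejected = res.p <= analysis.alpha
                rejections += rejected
                if {i, j} == {i_ctrl, i_lesion}:
                    lesion_pair_rej += rejected
        arrs = np.array([g.as_array() for g in ds.groups])
        means = arrs.mean(axis=1)
        mse = arrs.var(axis=1, ddof=1).mean()
        if mse > 0:
            q = np.abs(means[iu[0]] - means[iu[1]]) / np.sqrt(mse / n)
            if (q >= q_crit).any():
                fwer_hits += 1

    row = {
        "scenario": scenario,
        "reps": reps,
        "n_per_group": scen_cfg.n_per_group,
        "alpha": analysis.alpha,
        "per_pair_rejection": rejections / cells,
        "lesion_pair_rejection": lesion_pair_rej / reps,
        "tukey_fwer": fwer_hits / reps,
    }
    for t in TestName:
        row[f"frac_{t.value}"] = usage[t] / cells
    return pd.DataFrame([row])
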
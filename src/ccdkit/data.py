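"""Data model and I/O for multi-group study tables.

A study is a long-format table with one row per animal per endpoint:
``group,endpoint,value``.  Group display order is the order of first
appearance in the file and is preserved through every downstream
operation — the figures of a factorial animal study follow the
experimental layout (vehicle arm first, lesioned arm second), not an
alphabetical or magnitude sort.

Factor annotations (lesion status, herbal-extract treatment) are supplied
through an explicit design mapping rather than parsed out of group labels,
because label parsing is fragile across spelling variants.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .exceptions import NotFoundError, SchemaError, ValidationError

__all__ = [
    "Extract",
    "GroupData",
    "StudyDataset",
    "GroupSummary",
    "AnalysisConfig",
    "NormalityRule",
    "DEFAULT_DESIGN",
    "load_study",
    "write_study",
    "summarize",
    "load_config",
]

REQUIRED_COLUMNS = ("group", "endpoint", "value")


class Extract(str, enum.Enum):
    """Herbal-extract treatment factor."""

    NONE = "none"
    CENTELLA = "centella"
    WITHANIA = "withania"
    BOTH = "both"


class NormalityRule(str, enum.Enum):
    """How the three normality-test outcomes combine into one verdict."""

    ANY = "any"        # non-normal if any test rejects (conservative)
    MAJORITY = "majority"
    ALL = "all"        # non-normal only if every test rejects


#: Factor annotations for the eight standard group labels of the
#: lesion x extract factorial design (saline quartet then MPTP quartet).
DEFAULT_DESIGN: dict[str, tuple[bool, Extract]] = {
    "No Herbal Ext.": (False, Extract.NONE),
    "Centella Ext.": (False, Extract.CENTELLA),
    "Withania Ext.": (False, Extract.WITHANIA),
    "Withania & Centella Ext.": (False, Extract.BOTH),
    "MPTP No Herbal Ext.": (True, Extract.NONE),
    "MPTP Centella Ext.": (True, Extract.CENTELLA),
    "MPTP Withania Ext.": (True, Extract.WITHANIA),
    "MPTP Withania & Centella Ext.": (True, Extract.BOTH),
}


@dataclass(frozen=True)
class GroupData:
    """One experimental group: label, design factors and raw values."""

    label: str
    values: tuple[float, ...]
    lesion: bool = False
    extract: Extract = Extract.NONE

    def __post_init__(self) -> None:
        if len(self.values) == 0:
            raise ValidationError(f"group {self.label!r} has no values")
        vals = tuple(float(v) for v in self.values)
        if not all(math.isfinite(v) for v in vals):
            raise ValidationError(f"group {self.label!r} contains non-finite values")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "extract", Extract(self.extract))

    @property
    def n(self) -> int:
        return len(self.values)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass(frozen=True)
class StudyDataset:
    """All groups of one endpoint, in display order."""

    endpoint: str
    groups: tuple[GroupData, ...]
    units: str = ""

    def __post_init__(self) -> None:
        groups = tuple(self.groups)
        if len(groups) < 2:
            raise ValidationError("a study dataset needs at least two groups")
        labels = [g.label for g in groups]
        if len(set(labels)) != len(labels):
            raise ValidationError("group labels must be unique within a dataset")
        object.__setattr__(self, "groups", groups)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(g.label for g in self.groups)

    def group(self, label: str) -> GroupData:
        for g in self.groups:
            if g.label == label:
                return g
        raise NotFoundError(f"no group labelled {label!r}")

    def subset(self, labels: Iterable[str]) -> "StudyDataset":
        """Sub-study restricted to ``labels``, keeping their given order."""
        return replace(self, groups=tuple(self.group(l) for l in labels))


@dataclass(frozen=True)
class GroupSummary:
    """Mean, sample standard deviation (n-1 denominator) and count."""

    mean: float
    sd: float
    n: int
    degenerate: bool = False  # single observation: sd reported as 0


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the comparison engine.

    alpha
        Significance threshold; the boundary is inclusive (p equal to
        alpha counts as significant).
    normality_rule
        Aggregation of the three normality tests (default: any rejection
        marks the sample non-normal).
    exact_mw_threshold
        Largest combined sample size for which the Mann-Whitney p-value
        is computed by exact enumeration (ties always force the
        asymptotic path).
    mc_draws
        Monte-Carlo sample size for the Dunnett equicoordinate
        multivariate-t probability.
    strict_student_t
        If true, the first displayed p-value of every branch is always
        the pooled Student t-test, regardless of the assumption checks.
    levene_center
        "mean" for classic Levene, "median" for the Brown-Forsythe
        variant.
    """

    alpha: float = 0.05
    normality_rule: NormalityRule = NormalityRule.ANY
    exact_mw_threshold: int = 20
    mc_draws: int = 100_000
    seed: int = 0
    strict_student_t: bool = False
    levene_center: str = "mean"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError(f"alpha must be in (0,1), got {self.alpha}")
        object.__setattr__(self, "normality_rule", NormalityRule(self.normality_rule))
        if self.exact_mw_threshold < 2:
            raise ValidationError("exact_mw_threshold must be >= 2")
        if self.mc_draws < 1:
            raise ValidationError("mc_draws must be positive")
        if self.levene_center not in ("mean", "median"):
            raise ValidationError("levene_center must be 'mean' or 'median'")


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file {path} does not exist")
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except Exception as exc:  # malformed delimited text
        raise SchemaError(f"could not parse {path}: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path} is missing required column(s): {', '.join(missing)}")
    return df


def load_study(
    path: str | Path,
    endpoint: str,
    design: Mapping[str, tuple[bool, Extract | str]] | None = None,
    units: str = "",
) -> StudyDataset:
    """Read one endpoint's groups from a long-format CSV/TSV table.

    Parameters
    ----------
    path
        Delimited text file with header columns ``group,endpoint,value``.
    endpoint
        Which endpoint's rows to keep (e.g. ``"SOD"``, ``"Akinesia"``).
    design
        Mapping of group label to ``(lesion, extract)``.  Labels absent
        from the mapping get ``(False, none)``.  Defaults to the standard
        eight-group factorial annotation.
    """
    df = _read_table(path)
    design = DEFAULT_DESIGN if design is None else dict(design)

    sub = df[df["endpoint"] == endpoint]
    if sub.empty:
        raise NotFoundError(f"endpoint {endpoint!r} not present in {path}")

    # validate numeric values, reporting the 1-based data row of the offender
    values = pd.to_numeric(sub["value"], errors="coerce")
    bad = values.isna() | ~np.isfinite(values.to_numpy(dtype=float, na_value=np.nan))
    if bad.any():
        row = int(sub.index[bad.to_numpy()][0]) + 2  # +1 header, +1 one-based
        raise SchemaError(
            f"non-numeric value {sub['value'][bad].iloc[0]!r} in row {row} of {path}"
        )

    groups: list[GroupData] = []
    for label in sub["group"].drop_duplicates():  # first-appearance order
        vals = values[sub["group"] == label]
        if vals.empty:
            raise ValidationError(f"group {label!r} has no rows for {endpoint!r}")
        lesion, extract = design.get(label, (False, Extract.NONE))
        groups.append(
            GroupData(label=label, values=tuple(vals), lesion=bool(lesion),
                      extract=Extract(extract))
        )
    return StudyDataset(endpoint=endpoint, groups=tuple(groups), units=units)


def write_study(dataset: StudyDataset, path: str | Path) -> Path:
    """Write a dataset back to long-format delimited text (inverse of load)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    rows = [
        {"group": g.label, "endpoint": dataset.endpoint, "value": v}
        for g in dataset.groups
        for v in g.values
    ]
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)).to_csv(path, sep=sep, index=False)
    return path


def summarize(group: GroupData) -> GroupSummary:
    """Mean, sample sd (n-1 denominator) and n for one group.

    A single observation yields sd 0 with the ``degenerate`` flag set so
    that figure code can annotate rather than crash.
    """
    x = group.as_array()
    if x.size == 0:
        raise ValidationError("cannot summarize an empty group")
    if x.size == 1:
        return GroupSummary(mean=float(x[0]), sd=0.0, n=1, degenerate=True)
    return GroupSummary(mean=float(x.mean()), sd=float(x.std(ddof=1)), n=int(x.size))


def load_config(path: str | Path) -> tuple[AnalysisConfig, dict[str, tuple[bool, Extract]]]:
    """Read an :class:`AnalysisConfig` plus group design mapping from YAML.

    Recognised top-level keys: any :class:`AnalysisConfig` field, and an
    optional ``groups`` mapping ``label -> {lesion: bool, extract: str}``.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise SchemaError(f"config {path} must be a mapping")
    groups_raw = raw.pop("groups", {}) or {}
    design: dict[str, tuple[bool, Extract]] = {}
    for label, ann in groups_raw.items():
        try:
            design[str(label)] = (bool(ann.get("lesion", False)),
                                  Extract(ann.get("extract", "none")))
        except (AttributeError, ValueError) as exc:
            raise SchemaError(f"bad group annotation for {label!r}: {exc}") from exc
    allowed = set(AnalysisConfig.__dataclass_fields__)
    unknown = set(raw) - allowed
    if unknown:
        raise SchemaError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    return AnalysisConfig(**raw), design
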
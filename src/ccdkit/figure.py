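"""Rendering: annotated bar panel and the staircase comparison ladder.

The composite figure mirrors the conventions of factorial animal-study
panels: bars show group means with standard-deviation error bars, each
raw observation is drawn as a short horizontal line at its value, a solid
light-blue line under the axis spans the lesioned (MPTP) groups with a
black line spanning the vehicle groups, and a dotted line marks
extract-treated groups; sample sizes are printed under the bars.

To the right, the staircase ladder shows every pairwise comparison as a
"branch": tier *i* (anchored at the i-th displayed group) holds one
branch to each later group, stacked at strictly increasing heights so no
two branches collide.  Each branch carries three p-value strings (the
selected pair test, Tukey HSD, Dunnett) and is drawn dotted exactly when
its Tukey HSD p is at or below the significance threshold.

SVG output is the determinism surface: renders of identical inputs are
byte-identical (hash salt pinned, date metadata stripped).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
import matplotlib.pyplot as plt
import numpy as np

from .assumptions import NormalityVerdict, qq_points
from .data import GroupData, StudyDataset, summarize
from .exceptions import ValidationError
from .multicomp import ComparisonMatrix

__all__ = [
    "FigureStyle",
    "Branch",
    "Tier",
    "LadderLayout",
    "layout_ladder",
    "format_p",
    "render_bar_panel",
    "render_ccd",
    "render_normality_panel",
]

_SVG_HASHSALT = "ccdkit"


@dataclass(frozen=True)
class FigureStyle:
    """Visual conventions applied uniformly across panels of one figure."""

    alpha: float = 0.05
    sd_error_bars: bool = True
    show_datapoints: bool = True
    show_n: bool = True
    bar_color: str = "0.85"
    bar_edge: str = "black"
    mptp_line_color: str = "lightblue"
    saline_line_color: str = "black"
    extract_line_color: str = "black"
    p_fontsize: float = 4.0
    label_fontsize: float = 6.0
    dpi: int = 200


@dataclass(frozen=True)
class Branch:
    anchor: str
    target: str
    level: int                 # vertical slot, unique across the ladder
    span: tuple[int, int]      # display indices (anchor, target)
    line_style: str            # "solid" | "dotted"
    p_strings: tuple[str, str, str]  # top-to-bottom: selected, Tukey, Dunnett


@dataclass(frozen=True)
class Tier:
    anchor: str
    branches: tuple[Branch, ...]


@dataclass(frozen=True)
class LadderLayout:
    tiers: tuple[Tier, ...]

    @property
    def branches(self) -> tuple[Branch, ...]:
        return tuple(b for t in self.tiers for b in t.branches)


def format_p(p: float) -> str:
    """Render a p-value to 3 significant digits with a ``<0.001`` floor."""
    if not (0.0 <= p <= 1.0):
        raise ValidationError(f"p-value {p} outside [0,1]")
    if p < 0.001:
        return "<0.001"
    s = f"{p:.3g}"
    if float(s) >= 1.0:
        return "1.00"
    return s


def _branch_p_strings(comp) -> tuple[str, str, str]:
    def fmt(p: float) -> str:
        return format_p(p) if np.isfinite(p) else "n/a"

    top = fmt(comp.selected.p) if comp.selected is not None else "n/a"
    return (top, fmt(comp.p_tukey), fmt(comp.p_dunnett))


def layout_ladder(matrix: ComparisonMatrix, display_order: list[str] | None = None) -> LadderLayout:
    """Plan the staircase geometry from a complete comparison matrix.

    Tier *i* (anchored at the i-th group of ``display_order``) holds
    branches to groups i+1..K in order; vertical levels increase
    monotonically through the tiers so no two branches share a slot.
    """
    order = list(display_order) if display_order is not None else list(matrix.labels)
    if sorted(order) != sorted(matrix.labels):
        raise ValidationError("display_order does not match the matrix groups")
    index = {lbl: i for i, lbl in enumerate(order)}
    level = 0
    tiers: list[Tier] = []
    for i, anchor in enumerate(order[:-1]):
        branches: list[Branch] = []
        for target in order[i + 1:]:
            comp = matrix.pair(anchor, target)
            level += 1
            branches.append(Branch(
                anchor=anchor,
                target=target,
                level=level,
                span=(index[anchor], index[target]),
                line_style="dotted" if comp.tukey_significant else "solid",
                p_strings=_branch_p_strings(comp),
            ))
        tiers.append(Tier(anchor=anchor, branches=tuple(branches)))
    return LadderLayout(tiers=tuple(tiers))


def _factor_runs(flags: list[bool]) -> list[tuple[int, int]]:
    """Contiguous index runs where the flag is true (inclusive bounds)."""
    runs, start = [], None
    for i, f in enumerate(flags):
        if f and start is None:
            start = i
        elif not f and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(flags) - 1))
    return runs


def render_bar_panel(ax: plt.Axes, dataset: StudyDataset, style: FigureStyle | None = None) -> None:
    """Draw the annotated bar panel for one endpoint onto ``ax``."""
    style = style or FigureStyle()
    summaries = [summarize(g) for g in dataset.groups]
    x = np.arange(len(dataset.groups))
    means = [s.mean for s in summaries]
    sds = [s.sd for s in summaries]

    ax.bar(x, means, width=0.62, color=style.bar_color, edgecolor=style.bar_edge,
           linewidth=0.8, zorder=2)
    if style.sd_error_bars:
        ax.errorbar(x, means, yerr=sds, fmt="none", ecolor="black",
                    elinewidth=0.8, capsize=3, zorder=3)
    if style.show_datapoints:
        for xi, g in zip(x, dataset.groups):
            ax.plot(np.full(g.n, xi), g.values, marker="_", linestyle="none",
                    markersize=9, markeredgewidth=0.7, color="black", zorder=4)

    import matplotlib.transforms as mtransforms
    trans = mtransforms.blended_transform_factory(ax.transData, ax.transAxes)
    lesion = [g.lesion for g in dataset.groups]
    for lo, hi in _factor_runs(lesion):
        ax.plot([lo - 0.35, hi + 0.35], [-0.16, -0.16], transform=trans,
                color=style.mptp_line_color, linewidth=2.2, solid_capstyle="butt",
                clip_on=False, gid="ccd-mptp-line")
    for lo, hi in _factor_runs([not f for f in lesion]):
        ax.plot([lo - 0.35, hi + 0.35], [-0.16, -0.16], transform=trans,
                color=style.saline_line_color, linewidth=1.4, solid_capstyle="butt",
                clip_on=False, gid="ccd-saline-line")
    treated = [g.extract.value != "none" for g in dataset.groups]
    for lo, hi in _factor_runs(treated):
        ax.plot([lo - 0.35, hi + 0.35], [-0.20, -0.20], transform=trans,
                color=style.extract_line_color, linewidth=1.0, linestyle=(0, (2, 2)),
                clip_on=False, gid="ccd-extract-line")
    if style.show_n:
        for xi, s in zip(x, summaries):
            ax.text(xi, -0.10, str(s.n), transform=trans, ha="center", va="top",
                    fontsize=style.label_fontsize, gid="ccd-n-label")

    ax.set_xticks(x)
    ax.set_xticklabels([g.label for g in dataset.groups], rotation=60, ha="right",
                       fontsize=style.label_fontsize)
    ylabel = dataset.endpoint + (f" ({dataset.units})" if dataset.units else "")
    ax.set_ylabel(ylabel, fontsize=style.label_fontsize + 1)
    ax.tick_params(axis="y", labelsize=style.label_fontsize)
    ax.spines[["top", "right"]].set_visible(False)


def _draw_ladder(ax: plt.Axes, layout: LadderLayout, order: tuple[str, ...],
                 style: FigureStyle) -> None:
    n_levels = len(layout.branches)
    tick = 0.30
    for b in layout.branches:
        x0, x1 = b.span
        y = b.level
        ls = (0, (2, 2)) if b.line_style == "dotted" else "solid"
        ax.plot([x0, x0, x1, x1], [y - tick, y, y, y - tick], color="black",
                linewidth=0.8, linestyle=ls, gid=f"ccd-branch-{b.anchor}--{b.target}")
        xm = (x0 + x1) / 2.0
        for k, txt in enumerate(b.p_strings):
            ax.text(xm, y - 0.04 - 0.26 * k, txt, ha="center", va="top",
                    fontsize=style.p_fontsize, gid="ccd-branch-p")
    ax.set_xlim(-0.6, len(order) - 0.4)
    ax.set_ylim(0, n_levels + 1)
    ax.set_xticks(np.arange(len(order)))
    ax.set_xticklabels(order, rotation=60, ha="right", fontsize=style.label_fontsize)
    ax.set_yticks([])
    for side in ("top", "right", "left"):
        ax.spines[side].set_visible(False)


def _deterministic_save(fig: plt.Figure, out: Path, dpi: int) -> None:
    with matplotlib.rc_context({"svg.hashsalt": _SVG_HASHSALT,
                                "svg.fonttype": "none"}):
        if out.suffix.lower() == ".svg":
            fig.savefig(out, metadata={"Date": None})
        elif out.suffix.lower() == ".pdf":
            fig.savefig(out, metadata={"CreationDate": None})
        else:
            fig.savefig(out, dpi=dpi)


def render_ccd(
    dataset: StudyDataset,
    matrix: ComparisonMatrix,
    layout: LadderLayout | None = None,
    style: FigureStyle | None = None,
    out: str | Path = "ccd.svg",
) -> Path:
    """Write the composite figure: bar panel left, comparison ladder right."""
    style = style or FigureStyle()
    layout = layout if layout is not None else layout_ladder(matrix)
    out = Path(out)

    fig, (ax_bar, ax_ladder) = plt.subplots(
        1, 2, figsize=(10, 4.5), width_ratios=[1.0, 1.3],
        constrained_layout=True)
    try:
        render_bar_panel(ax_bar, dataset, style)
        _draw_ladder(ax_ladder, layout, tuple(matrix.labels), style)
        fig.suptitle(dataset.endpoint, fontsize=style.label_fontsize + 2)
        _deterministic_save(fig, out, style.dpi)
    finally:
        plt.close(fig)
    return out


def render_normality_panel(
    values, verdict: NormalityVerdict, out: str | Path, title: str = ""
) -> Path:
    """QQ plot and histogram-with-normal-overlay diagnostic for one sample."""
    from scipy import stats as _st

    x = np.asarray(values, dtype=float)
    pts = qq_points(x)
    out = Path(out)
    fig, (ax_qq, ax_hist) = plt.subplots(1, 2, figsize=(7, 3), constrained_layout=True)
    try:
        ax_qq.plot(pts[:, 0], pts[:, 1], "o", markersize=3, color="black")
        mu, sd = x.mean(), x.std(ddof=1)
        span = np.array([pts[0, 0], pts[-1, 0]])
        ax_qq.plot(span, mu + sd * span, "-", linewidth=0.8, color="steelblue")
        ax_qq.set_xlabel("theoretical quantile", fontsize=7)
        ax_qq.set_ylabel("ordered value", fontsize=7)

        nbins = max(5, min(15, x.size // 2))
        ax_hist.hist(x, bins=nbins, density=True, color="0.85", edgecolor="black")
        if sd > 0:
            grid = np.linspace(x.min() - sd, x.max() + sd, 200)
            ax_hist.plot(grid, _st.norm.pdf(grid, mu, sd), color="steelblue", linewidth=1)
        ax_hist.set_xlabel("value", fontsize=7)
        ax_hist.set_ylabel("density", fontsize=7)

        lines = [f"{r.test.value}: p={format_p(r.p)}" for r in verdict.results]
        lines.append(f"verdict ({verdict.rule_used.value} rule): "
                     + ("normal" if verdict.is_normal else "non-normal"))
        fig.suptitle((title + "  " if title else "") + " | ".join(lines), fontsize=6)
        for ax in (ax_qq, ax_hist):
            ax.tick_params(labelsize=6)
        _deterministic_save(fig, out, 200)
    finally:
        plt.close(fig)
    return out
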
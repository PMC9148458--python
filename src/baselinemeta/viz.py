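"""Rank-ordered forest plot with guideline overlay, and the funnel plot.

The forest plot puts coded baseline SMD on the x-axis and cumulative
probability k/(n+1) on the y-axis.  Each trial is a square centred at
(smd, percentile) whose area is proportional to its inverse-variance
weight — filled black for a negative coded SMD (intervention arm better
at baseline), open for a non-negative one — with horizontal 95% CI
whiskers.  The guideline curve Phi(x/sd_guide) is drawn across the
plotted range, the fixed-effect pooled estimate appears as a diamond
spanning its 95% CI at probability 0.5, and a circular marker sits at
(0, 0.5) where the median of a well-randomized corpus should fall.

The funnel plot puts SMD against SE (SE = 0 at the top) with two
pseudo-95% funnels — around zero and around the pooled estimate — and,
when a trend was fitted, the regression line of SMD on SE.

SVG is the canonical output: every plotted element carries a stable
``gid`` so the document tree is structurally testable, and rendering is
byte-deterministic for identical inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.patches import Polygon, Rectangle

from .diagnostics import GuidelineCurve, RankedEffects, TrendResult
from .effects import EffectEstimate
from .pooling import PooledResult, Z_95

__all__ = ["PlotSpec", "forest_plot", "funnel_plot", "pseudo_ci_bounds"]

# stable glyph ids in the emitted SVG
matplotlib.rcParams["svg.hashsalt"] = "baselinemeta"


@dataclass(frozen=True)
class PlotSpec:
    width: float = 7.0
    height: float = 5.0
    format: Literal["svg", "png"] = "svg"
    x_range: tuple[float, float] | None = None
    max_square_pts: float = 14.0  # side of the heaviest trial's square, in points
    annotate: bool = True


def pseudo_ci_bounds(se, center: float = 0.0):
    """Pseudo-95% funnel bounds ``center +/- 1.96 se`` (vectorized)."""
    se = np.asarray(se, dtype=float)
    half = Z_95 * se
    return center - half, center + half


def _save(fig, path: str | Path, spec: PlotSpec) -> None:
    path = Path(path)
    fmt = path.suffix.lstrip(".").lower() or spec.format
    kwargs = {}
    if fmt == "svg":
        kwargs["metadata"] = {"Date": None}  # drop the timestamp for determinism
    fig.savefig(path, format=fmt, **kwargs)
    plt.close(fig)


def forest_plot(
    ranked: RankedEffects,
    curve: GuidelineCurve,
    pooled: PooledResult,
    path: str | Path,
    spec: PlotSpec | None = None,
) -> Path:
    """Render the rank-ordered cumulative-probability forest plot."""
    spec = spec or PlotSpec()
    fig, ax = plt.subplots(figsize=(spec.width, spec.height))

    ci_lo = min(e.ci_low for e in ranked.entries)
    ci_hi = max(e.ci_high for e in ranked.entries)
    guide_half = 3.5 * curve.sd_guide
    lo = min(ci_lo, pooled.ci_low, -guide_half, 0.0)
    hi = max(ci_hi, pooled.ci_high, guide_half, 0.0)
    if spec.x_range is not None:
        lo, hi = spec.x_range
    pad = 0.05 * (hi - lo)
    ax.set_xlim(lo - pad, hi + pad)
    ax.set_ylim(0.0, 1.0)

    # guideline: expected pattern under zero true difference everywhere
    xs = np.linspace(*ax.get_xlim(), 512)
    (curve_line,) = ax.plot(xs, curve(xs), color="#cc2222", lw=1.5, zorder=2)
    curve_line.set_gid("guideline-curve")

    # CI whiskers
    ys = [e.percentile for e in ranked.entries]
    whiskers = ax.hlines(
        ys,
        [e.ci_low for e in ranked.entries],
        [e.ci_high for e in ranked.entries],
        color="0.35",
        lw=0.9,
        zorder=3,
    )
    whiskers.set_gid("ci-whiskers")

    # weight-proportional squares (area ~ weight), black when smd < 0
    fig.canvas.draw()  # fix the layout so point->data conversion is stable
    bbox = ax.get_window_extent()
    x_per_pt = (ax.get_xlim()[1] - ax.get_xlim()[0]) / bbox.width * fig.dpi / 72.0
    y_per_pt = 1.0 / bbox.height * fig.dpi / 72.0
    w_max = max(e.weight for e in ranked.entries)
    for e in ranked.entries:
        side_pts = max(spec.max_square_pts * math.sqrt(e.weight / w_max), 2.0)
        sx, sy = side_pts * x_per_pt, side_pts * y_per_pt
        patch = Rectangle(
            (e.smd - sx / 2.0, e.percentile - sy / 2.0),
            sx,
            sy,
            facecolor="black" if e.smd < 0 else "white",
            edgecolor="black",
            lw=0.8,
            zorder=4,
        )
        patch.set_gid(f"square-{e.trial_id}")
        ax.add_patch(patch)

    # pooled diamond spanning the 95% CI at probability 0.5
    h = 0.03
    diamond = Polygon(
        [
            (pooled.ci_low, 0.5),
            (pooled.b_hat, 0.5 + h),
            (pooled.ci_high, 0.5),
            (pooled.b_hat, 0.5 - h),
        ],
        closed=True,
        facecolor="0.75",
        edgecolor="black",
        lw=0.9,
        zorder=5,
    )
    diamond.set_gid("pooled-diamond")
    ax.add_patch(diamond)

    (zero_marker,) = ax.plot(
        [0.0], [0.5], marker="o", ms=6, mfc="none", mec="#cc2222", ls="none", zorder=6
    )
    zero_marker.set_gid("zero-marker")

    ax.set_xlabel("baseline SMD (negative = intervention arm better)")
    ax.set_ylabel("cumulative probability  k/(n+1)")
    if spec.annotate:
        ax.set_title(
            f"k = {ranked.n};  pooled SMD = {pooled.b_hat:.3f} "
            f"[{pooled.ci_low:.3f}, {pooled.ci_high:.3f}];  I² = {pooled.i2:.1f}%"
        )
    _save(fig, path, spec)
    return Path(path)


def funnel_plot(
    effects: Sequence[EffectEstimate],
    pooled: PooledResult,
    trend: TrendResult | None,
    path: str | Path,
    spec: PlotSpec | None = None,
) -> Path:
    """Render the SMD-vs-SE funnel plot with pseudo-95% limits."""
    spec = spec or PlotSpec()
    fig, ax = plt.subplots(figsize=(spec.width, spec.height))
    smd = np.array([e.smd for e in effects])
    se = np.array([e.se for e in effects])
    se_top = float(se.max()) * 1.08

    pts = ax.scatter(smd, se, s=22, facecolor="none", edgecolor="black", zorder=4)
    pts.set_gid("funnel-points")

    se_grid = np.linspace(0.0, se_top, 64)
    for center, gid, color in ((0.0, "pseudo-ci-zero", "0.4"), (pooled.b_hat, "pseudo-ci-pooled", "#cc2222")):
        lo_line, hi_line = pseudo_ci_bounds(se_grid, center)
        xs = np.concatenate([lo_line[::-1], hi_line])
        ys = np.concatenate([se_grid[::-1], se_grid])
        (line,) = ax.plot(xs, ys, ls="--", lw=1.0, color=color, zorder=2)
        line.set_gid(gid)

    if trend is not None and trend.method == "ols_smd_on_se":
        (tl,) = ax.plot(
            trend.intercept + trend.slope * se_grid,
            se_grid,
            color="#2255cc",
            lw=1.4,
            zorder=3,
        )
        tl.set_gid("trend-line")
        if spec.annotate:
            ax.set_title(
                f"SMD-vs-SE trend: slope = {trend.slope:.3f}, p = {trend.p_trend:.4f} ({trend.direction})"
            )
    elif trend is not None and spec.annotate:
        ax.set_title(
            f"asymmetry intercept = {trend.slope:.3f}, p = {trend.p_trend:.4f} ({trend.direction})"
        )

    ax.set_ylim(se_top, 0.0)  # SE inverted: most precise trials at the top
    ax.set_xlabel("baseline SMD")
    ax.set_ylabel("standard error")
    _save(fig, path, spec)
    return Path(path)
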
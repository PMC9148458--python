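"""Rank-percentile forest diagnostics, guideline curve, shape call, funnel trend.

The diagnostic plot ranks the trials' coded baseline SMDs and plots the
k-th smallest at cumulative probability k/(n+1), turning the forest plot
into an empirical cumulative-probability plot.  Overlaid is the
"guideline" curve Phi(x / sd_guide) with sd_guide the standard error of
the fixed-effect pooled SMD: the pattern the trial estimates would trace
if every trial's true baseline difference were exactly zero and only the
pooled-level sampling variation remained.  Departures from the guideline
are informative:

* median of the coded SMDs away from zero with estimates off the curve
  in one direction only -> a *skewed* set, the signature of selective
  non-reporting of baselines on one side;
* median away from zero but estimates tracking the curve -> a *shifted*
  set, suggesting a systematic allocation problem;
* many per-trial CIs failing to reach the curve -> *overdispersion*,
  i.e. more between-trial variation than pure sampling error.

When skew is flagged, the funnel-trend stage regresses SMD on SE (or
runs the classical small-study asymmetry regression on precision) to ask
whether larger effects concentrate in smaller, noisier trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Literal, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .effects import EffectEstimate
from .pooling import Z_95

__all__ = [
    "GuidelineCurve",
    "RankedEffects",
    "RankedEntry",
    "ShapeClassification",
    "ShapeThresholds",
    "TrendResult",
    "classify_shape",
    "funnel_trend",
    "guideline_curve",
    "rank_percentiles",
]

TrendMethod = Literal["ols_smd_on_se", "egger"]


@dataclass(frozen=True)
class RankedEntry:
    trial_id: str
    smd: float
    se: float
    ci_low: float
    ci_high: float
    weight: float
    percentile: float
    rank: int


@dataclass(frozen=True)
class RankedEffects:
    """Effects sorted for the cumulative-probability forest plot.

    ``entries`` run from the largest SMD (top of the plot, percentile
    n/(n+1)) down to the smallest (percentile 1/(n+1)); ``rank`` is the
    ascending rank k, so percentile == k/(n+1) exactly.
    """

    entries: tuple[RankedEntry, ...]
    n: int


def rank_percentiles(effects: Sequence[EffectEstimate]) -> RankedEffects:
    """Order effects for plotting and attach k/(n+1) plotting positions.

    Ties in SMD are broken by ascending SE, then trial_id, the more
    precise trial taking the higher position.  Per-trial 95% CI is
    smd +/- 1.96 se.
    """
    if not effects:
        raise ValueError("rank_percentiles requires at least one effect")
    n = len(effects)
    ordered = sorted(effects, key=lambda e: (-e.smd, e.se, e.trial_id))
    entries = []
    for j, e in enumerate(ordered):  # j = 0 at the top of the plot
        k = n - j
        entries.append(
            RankedEntry(
                trial_id=e.trial_id,
                smd=e.smd,
                se=e.se,
                ci_low=e.smd - Z_95 * e.se,
                ci_high=e.smd + Z_95 * e.se,
                weight=e.weight,
                percentile=k / (n + 1),
                rank=k,
            )
        )
    return RankedEffects(entries=tuple(entries), n=n)


@dataclass(frozen=True)
class GuidelineCurve:
    """The zero-mean cumulative normal guideline Phi(x / sd_guide).

    ``sd_guide`` is the fixed-effect pooled standard error — the spread
    the rank-ordered estimates would show if every trial's true baseline
    difference were zero with only pooled-level sampling variation.
    """

    sd_guide: float

    def __call__(self, x):
        return stats.norm.cdf(np.asarray(x, dtype=float) / self.sd_guide)

    def quantile(self, p):
        """Inverse: abscissa whose guideline probability is p."""
        return self.sd_guide * stats.norm.ppf(np.asarray(p, dtype=float))


def guideline_curve(var_b: float) -> GuidelineCurve:
    if not var_b > 0:
        raise ValueError(f"var_b must be > 0, got {var_b}")
    return GuidelineCurve(sd_guide=math.sqrt(var_b))


@dataclass(frozen=True)
class ShapeThresholds:
    """Operational cut-offs turning the visual shape call into a rule."""

    alpha_median: float = 0.10
    excess_min: float = 0.30
    coverage_min: float = 0.80


ShapeLabel = Literal["aligned", "shifted", "overdispersed", "skewed_right", "skewed_left"]


@dataclass(frozen=True)
class ShapeClassification:
    """Rule-based reading of the rank-ordered plot against the guideline."""

    label: ShapeLabel
    median_smd: float
    median_sign_p: float
    guideline_coverage: float
    one_sided_excess: float
    criteria_trace: dict[str, Any] = field(default_factory=dict)


def classify_shape(
    ranked: RankedEffects,
    curve: GuidelineCurve,
    thresholds: ShapeThresholds | None = None,
) -> ShapeClassification:
    """Classify the rank-ordered SMD pattern against the guideline curve.

    Each trial is compared at its own plotting position: the guideline
    abscissa x_k = sd_guide * Phi^{-1}(k/(n+1)).  Three ingredients feed
    the rule: an exact binomial sign test of median(SMD) = 0 (zeros
    dropped); the fraction of per-trial 95% CIs that enclose their x_k
    (guideline coverage); and the signed excess of point estimates right
    of their x_k minus left of it.

    Default rule: skewed (right/left by the sign of the excess) when the
    median test rejects at alpha_median and |excess| >= excess_min; else
    shifted when the median test rejects; else overdispersed when
    coverage < coverage_min; else aligned.
    """
    th = thresholds or ShapeThresholds()
    smds = np.array([e.smd for e in ranked.entries])
    median_smd = float(np.median(smds))
    n_neg = int(np.sum(smds < 0))
    n_pos = int(np.sum(smds > 0))
    if n_neg + n_pos == 0:
        median_p = 1.0
    else:
        median_p = float(stats.binomtest(n_neg, n_neg + n_pos, 0.5).pvalue)

    x_k = np.array([curve.quantile(e.percentile) for e in ranked.entries])
    ci_low = np.array([e.ci_low for e in ranked.entries])
    ci_high = np.array([e.ci_high for e in ranked.entries])
    coverage = float(np.mean((ci_low <= x_k) & (x_k <= ci_high)))
    excess = float(np.mean(smds > x_k) - np.mean(smds < x_k))

    trace: dict[str, Any] = {
        "n": ranked.n,
        "n_negative": n_neg,
        "n_positive": n_pos,
        "n_zero": ranked.n - n_neg - n_pos,
        "shift_direction": "negative" if median_smd < 0 else ("positive" if median_smd > 0 else "none"),
        "thresholds": {
            "alpha_median": th.alpha_median,
            "excess_min": th.excess_min,
            "coverage_min": th.coverage_min,
        },
        "notes": [],
    }
    if ranked.n < 3:
        trace["notes"].append("fewer than 3 effects: low-information, defaulting to aligned")
        label: ShapeLabel = "aligned"
    elif median_p < th.alpha_median and abs(excess) >= th.excess_min:
        label = "skewed_right" if excess > 0 else "skewed_left"
    elif median_p < th.alpha_median:
        label = "shifted"
    elif coverage < th.coverage_min:
        label = "overdispersed"
    else:
        label = "aligned"
    trace["coverage_reading"] = (
        "per-trial CIs compared against the guideline abscissa at each trial's own percentile"
    )
    return ShapeClassification(
        label=label,
        median_smd=median_smd,
        median_sign_p=median_p,
        guideline_coverage=coverage,
        one_sided_excess=excess,
        criteria_trace=trace,
    )


@dataclass(frozen=True)
class TrendResult:
    """Linear SMD-vs-SE trend (or classical asymmetry regression) result."""

    method: TrendMethod
    slope: float
    intercept: float
    slope_se: float
    p_trend: float
    direction: Literal["increasing_with_se", "decreasing_with_se", "none"]
    alpha_trend: float = 0.10


def funnel_trend(
    effects: Sequence[EffectEstimate],
    method: TrendMethod = "ols_smd_on_se",
    alpha_trend: float = 0.10,
) -> TrendResult:
    """Test for a linear trend of coded SMDs with their standard errors.

    ``ols_smd_on_se`` fits smd_i = a + b se_i and t-tests b.  ``egger``
    fits the precision form smd_i/se_i = b0 + b1 (1/se_i); its intercept
    b0 is the small-study asymmetry statistic and carries the same units
    as the slope b above.  Direction is reported only when the tested
    coefficient is significant at ``alpha_trend``.
    """
    if len(effects) < 3:
        raise ValueError("funnel trend requires at least 3 effects")
    smd = np.array([e.smd for e in effects])
    se = np.array([e.se for e in effects])
    if np.ptp(se) == 0:
        raise ValueError("all standard errors identical: no identifiable SMD-vs-SE trend")
    if method == "ols_smd_on_se":
        X = sm.add_constant(se)
        fit = sm.OLS(smd, X).fit()
        intercept, slope = fit.params
        slope_se = float(fit.bse[1])
        p = float(fit.pvalues[1])
    elif method == "egger":
        X = sm.add_constant(1.0 / se)
        fit = sm.OLS(smd / se, X).fit()
        slope, _b1 = fit.params  # intercept of the precision regression
        intercept = float(_b1)
        slope_se = float(fit.bse[0])
        p = float(fit.pvalues[0])
    else:
        raise ValueError(f"unknown trend method {method!r}")
    slope = float(slope)
    intercept = float(intercept)
    if slope_se == 0.0 or math.isnan(p):  # perfectly collinear data
        p = 0.0 if slope != 0.0 else 1.0
    if p < alpha_trend:
        direction = "increasing_with_se" if slope > 0 else "decreasing_with_se"
    else:
        direction = "none"
    return TrendResult(
        method=method,
        slope=slope,
        intercept=intercept,
        slope_se=slope_se,
        p_trend=p,
        direction=direction,
        alpha_trend=alpha_trend,
    )
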
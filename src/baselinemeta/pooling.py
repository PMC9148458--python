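"""Fixed-effect pooling, heterogeneity, and the sign-proportion test.

Under well-performed randomization the true baseline difference is zero
in every trial, so a fixed-effect model is the natural reference: the
pooled baseline SMD is the inverse-variance weighted mean

    b_hat = sum(w_i y_i) / sum(w_i),   w_i = 1 / v_i,

with var(b_hat) = 1 / sum(w_i) and a plain normal 95% CI.  Cochran's
Q = sum(w_i (y_i - b_hat)^2) and I^2 = max(0, (Q - df)/Q) * 100 quantify
between-trial heterogeneity of the baseline differences, itself a
possible sign of defective randomization.

The sign-proportion test asks whether negative coded SMDs (intervention
arm better at baseline) occur in half of the trials, via a one-proportion
z-test against 0.5; exact zeros are counted on neither side.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

from scipy import stats

from .effects import EffectEstimate

__all__ = [
    "FixedEffectPool",
    "PooledResult",
    "analyze_pooled",
    "heterogeneity",
    "i2_band",
    "i2_band_memberships",
    "pool_fixed",
    "sign_proportion_test",
]

logger = logging.getLogger(__name__)

Z_95 = 1.96  # conventional normal critical value for 95% CIs

# Conventional, overlapping I^2 interpretation ranges.
I2_OVERLAPPING_BANDS: tuple[tuple[str, float, float], ...] = (
    ("insignificant", 0.0, 40.0),
    ("moderate", 30.0, 60.0),
    ("substantial", 50.0, 90.0),
    ("considerable", 75.0, 100.0),
)

# Single-label cut points chosen so each I^2 maps to exactly one band.
_I2_LABEL_CUTS: tuple[tuple[str, float], ...] = (
    ("insignificant", 30.0),
    ("moderate", 50.0),
    ("substantial", 75.0),
    ("considerable", 100.0),
)


def i2_band(i2: float) -> str:
    """Single heterogeneity label: [0,30) insignificant, [30,50) moderate,
    [50,75) substantial, [75,100] considerable."""
    if not 0.0 <= i2 <= 100.0:
        raise ValueError(f"I^2 must lie in [0, 100], got {i2}")
    for label, upper in _I2_LABEL_CUTS:
        if i2 < upper:
            return label
    return "considerable"


def i2_band_memberships(i2: float) -> list[str]:
    """All conventional (overlapping) ranges that contain this I^2."""
    return [name for name, lo, hi in I2_OVERLAPPING_BANDS if lo <= i2 <= hi]


@dataclass(frozen=True)
class FixedEffectPool:
    """Inverse-variance pooled estimate with its normal 95% CI."""

    b_hat: float
    var_b: float
    ci_low: float
    ci_high: float
    p_pooled: float
    k: int


@dataclass(frozen=True)
class PooledResult:
    """Full pooled summary: estimate, heterogeneity, and sign statistics."""

    b_hat: float
    var_b: float
    ci_low: float
    ci_high: float
    p_pooled: float
    k: int
    q: float
    df: int
    i2: float
    i2_band: str
    i2_bands_overlapping: tuple[str, ...]
    prop_negative: float
    n_negative: int
    n_positive: int
    n_zero: int
    z_sign: float
    p_sign: float


def pool_fixed(effects: Sequence[EffectEstimate]) -> FixedEffectPool:
    """Fixed-effect inverse-variance pooled SMD with 95% CI and z-based p."""
    if not effects:
        raise ValueError("cannot pool an empty collection of effects")
    w_sum = 0.0
    wy_sum = 0.0
    for e in effects:
        w_sum += e.weight
        wy_sum += e.weight * e.smd
    b_hat = wy_sum / w_sum
    var_b = 1.0 / w_sum
    se = math.sqrt(var_b)
    z = b_hat / se
    p = 2.0 * stats.norm.sf(abs(z))
    return FixedEffectPool(
        b_hat=b_hat,
        var_b=var_b,
        ci_low=b_hat - Z_95 * se,
        ci_high=b_hat + Z_95 * se,
        p_pooled=float(p),
        k=len(effects),
    )


def heterogeneity(
    effects: Sequence[EffectEstimate], b_hat: float
) -> tuple[float, int, float, str]:
    """Cochran's Q, its df, I^2 (%) and the single-label heterogeneity band."""
    if not effects:
        raise ValueError("heterogeneity requires at least one effect")
    k = len(effects)
    q = sum(e.weight * (e.smd - b_hat) ** 2 for e in effects)
    df = k - 1
    if k == 1:
        logger.info("heterogeneity undefined for a single trial; reporting I^2 = 0")
        i2 = 0.0
    elif q > 0:
        i2 = max(0.0, (q - df) / q) * 100.0
    else:
        i2 = 0.0
    return q, df, i2, i2_band(i2)


def sign_proportion_test(
    effects: Sequence[EffectEstimate], continuity: bool = False
) -> tuple[float, float, float]:
    """One-proportion z-test of P(coded SMD < 0) = 1/2.

    Exact zeros are excluded from the denominator.  Returns
    ``(prop_negative, z, p_two_sided)``.
    """
    n_neg = sum(1 for e in effects if e.smd < 0)
    n_zero = sum(1 for e in effects if e.smd == 0)
    m = len(effects) - n_zero
    if m < 1:
        raise ValueError("sign test undefined: all effects are exactly zero")
    prop = n_neg / m
    se0 = math.sqrt(0.25 / m)
    diff = prop - 0.5
    if continuity and diff != 0.0:
        diff -= math.copysign(0.5 / m, diff)
    z = diff / se0
    p = 2.0 * stats.norm.sf(abs(z))
    return prop, z, float(p)


def analyze_pooled(
    effects: Sequence[EffectEstimate], continuity: bool = False
) -> PooledResult:
    """Pooling + heterogeneity + sign test in one result object."""
    pool = pool_fixed(effects)
    q, df, i2, band = heterogeneity(effects, pool.b_hat)
    n_neg = sum(1 for e in effects if e.smd < 0)
    n_pos = sum(1 for e in effects if e.smd > 0)
    n_zero = len(effects) - n_neg - n_pos
    if n_neg + n_pos >= 1:
        prop, z_sign, p_sign = sign_proportion_test(effects, continuity)
    else:  # all exact zeros: report a degenerate but well-defined summary
        prop, z_sign, p_sign = 0.0, 0.0, 1.0
    return PooledResult(
        b_hat=pool.b_hat,
        var_b=pool.var_b,
        ci_low=pool.ci_low,
        ci_high=pool.ci_high,
        p_pooled=pool.p_pooled,
        k=pool.k,
        q=q,
        df=df,
        i2=i2,
        i2_band=band,
        i2_bands_overlapping=tuple(i2_band_memberships(i2)),
        prop_negative=prop,
        n_negative=n_neg,
        n_positive=n_pos,
        n_zero=n_zero,
        z_sign=z_sign,
        p_sign=p_sign,
    )
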
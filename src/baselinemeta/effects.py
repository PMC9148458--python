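"""Reporting-status triage and direction-coded baseline SMDs.

The baseline difference between arms is expressed as a standardized mean
difference so that trials measuring their primary outcome on different
scales can be compared on one axis.  For a trial with arm means
``m_t, m_c``, SDs ``s_t, s_c`` and sizes ``n_t, n_c``::

    d = (m_t - m_c) / s_pooled,
    s_pooled^2 = ((n_t - 1) s_t^2 + (n_c - 1) s_c^2) / (n_t + n_c - 2)

Hedges' g applies the small-sample correction J = 1 - 3/(4 df - 1) with
df = n_t + n_c - 2.  The large-sample variance used for inverse-variance
weights is ``(n_t + n_c)/(n_t n_c) + smd^2 / (2 (n_t + n_c))``.

Direction coding: after computing the raw treatment-minus-control SMD on
the outcome's native scale, the sign is flipped for higher-is-better
outcomes, so a negative coded SMD always means the intervention arm was
in a better condition at baseline.

Only trials whose baseline summaries can be taken to describe the
randomized sample contribute an effect: trials that reported baselines
for analyzed patients only are admitted when overall dropout is below a
threshold (default 10%); median/IQR-only trials and non-reporting trials
are excluded but retained for reporting-rate statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

from .core import (
    ArmSummary,
    BaselinePopulation,
    Corpus,
    ReportingCategory,
    ReportingStatus,
    SummaryType,
    TrialRecord,
)

__all__ = [
    "ClassificationError",
    "CorpusEffects",
    "EffectEstimate",
    "classify_reporting",
    "corpus_effects",
    "orient_effect",
    "raw_smd",
    "reporting_rate",
]

SmdMethod = Literal["hedges_g", "cohens_d"]


class ClassificationError(ValueError):
    """Reporting status cannot be determined from the available counts."""


@dataclass(frozen=True)
class EffectEstimate:
    """A direction-coded baseline SMD with its variance and weight.

    ``smd < 0`` means the intervention arm was better off at baseline.
    ``se = sqrt(variance)`` and ``weight = 1/variance`` exactly.
    """

    trial_id: str
    smd: float
    variance: float
    n_total: int
    method: SmdMethod = "hedges_g"
    se: float = field(init=False)
    weight: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.variance > 0:
            raise ValueError(f"variance must be > 0, got {self.variance}")
        object.__setattr__(self, "se", math.sqrt(self.variance))
        object.__setattr__(self, "weight", 1.0 / self.variance)


def pooled_dropout_rate(trial: TrialRecord) -> float | None:
    """Overall dropout 1 - (analyzed total / randomized total); None if unknown."""
    t, c = trial.treatment, trial.control
    if t.n_analyzed is None or c.n_analyzed is None:
        return None
    n_rand = t.n_randomized + c.n_randomized
    # direct ratio of dropouts keeps the <threshold comparison exact at
    # round fractions like 20/200
    return (n_rand - (t.n_analyzed + c.n_analyzed)) / n_rand


def _per_arm_dropout_rates(trial: TrialRecord) -> tuple[float, float] | None:
    t, c = trial.treatment, trial.control
    if t.n_analyzed is None or c.n_analyzed is None:
        return None
    return (
        (t.n_randomized - t.n_analyzed) / t.n_randomized,
        (c.n_randomized - c.n_analyzed) / c.n_randomized,
    )


def classify_reporting(
    trial: TrialRecord,
    dropout_threshold: float = 0.10,
    per_arm: bool = False,
) -> ReportingStatus:
    """Triage a trial's baseline reporting into one of four categories.

    Precedence: not_reported > reported_median_excluded > the dropout
    rules.  Trials whose baseline summaries describe analyzed patients
    only are treated as representing the randomized sample when the
    dropout rate is strictly below ``dropout_threshold`` (pooled over
    arms by default; ``per_arm=True`` requires both arms below it).
    """
    types = (trial.treatment.summary_type, trial.control.summary_type)
    if SummaryType.NONE in types:
        return ReportingStatus(ReportingCategory.NOT_REPORTED, pooled_dropout_rate(trial))
    if SummaryType.MEDIAN_IQR in types:
        return ReportingStatus(ReportingCategory.REPORTED_MEDIAN_EXCLUDED, pooled_dropout_rate(trial))
    if trial.baseline_population is BaselinePopulation.ANALYZED_ONLY:
        rate = pooled_dropout_rate(trial)
        if rate is None:
            raise ClassificationError(
                f"trial {trial.trial_id!r}: analyzed-only baseline but n_analyzed missing; "
                "cannot compute the dropout rate"
            )
        if per_arm:
            rates = _per_arm_dropout_rates(trial)
            assert rates is not None
            below = max(rates) < dropout_threshold
        else:
            below = rate < dropout_threshold
        if below:
            return ReportingStatus(ReportingCategory.REPORTED_RANDOMIZED, rate)
        return ReportingStatus(ReportingCategory.REPORTED_ANALYZED_HIGH_DROPOUT, rate)
    # randomized population; unknown population is treated the same way
    # (extraction sheets often omit the flag when the trial had no dropout).
    return ReportingStatus(ReportingCategory.REPORTED_RANDOMIZED, pooled_dropout_rate(trial))


def reporting_rate(
    corpus: Corpus, dropout_threshold: float = 0.10
) -> tuple[float, dict[str, int]]:
    """Fraction of trials with usable randomized baselines, plus counts per status."""
    counts = {c.value: 0 for c in ReportingCategory}
    for trial in corpus:
        counts[classify_reporting(trial, dropout_threshold).status.value] += 1
    rate = counts[ReportingCategory.REPORTED_RANDOMIZED.value] / len(corpus)
    return rate, counts


def raw_smd(
    treatment: ArmSummary,
    control: ArmSummary,
    method: SmdMethod = "hedges_g",
    n_source: Literal["randomized", "analyzed"] = "randomized",
) -> tuple[float, float]:
    """Treatment-minus-control SMD on the native scale, with its variance.

    Returns ``(smd, variance)``.  The variance is the standard
    large-sample approximation evaluated at the returned (possibly
    bias-corrected) SMD.
    """
    for arm, name in ((treatment, "treatment"), (control, "control")):
        if arm.summary_type is not SummaryType.MEAN_SD:
            raise ValueError(f"{name} arm does not carry mean/sd summaries")
    if n_source == "analyzed":
        if treatment.n_analyzed is None or control.n_analyzed is None:
            raise ValueError("n_source='analyzed' but n_analyzed missing")
        n_t, n_c = treatment.n_analyzed, control.n_analyzed
    else:
        n_t, n_c = treatment.n_randomized, control.n_randomized
    if n_t + n_c <= 2:
        raise ValueError(f"insufficient sample: n_t + n_c = {n_t + n_c} <= 2")
    sd_t, sd_c = treatment.sd, control.sd
    assert sd_t is not None and sd_c is not None and treatment.mean is not None and control.mean is not None
    if sd_t == 0 and sd_c == 0:
        raise ValueError("degenerate scale: both arm SDs are zero")
    df = n_t + n_c - 2
    s_pooled = math.sqrt(((n_t - 1) * sd_t**2 + (n_c - 1) * sd_c**2) / df)
    d = (treatment.mean - control.mean) / s_pooled
    if method == "hedges_g":
        d *= 1.0 - 3.0 / (4.0 * df - 1.0)
    elif method != "cohens_d":
        raise ValueError(f"unknown SMD method {method!r}")
    n = n_t + n_c
    variance = n / (n_t * n_c) + d * d / (2.0 * n)
    return d, variance


def orient_effect(smd_raw: float, orientation) -> float:
    """Apply direction coding: flip the sign for higher-is-better outcomes."""
    from .core import Orientation

    orientation = Orientation(orientation)
    return -smd_raw if orientation is Orientation.HIGHER_IS_BETTER else smd_raw


@dataclass(frozen=True)
class CorpusEffects:
    """Admissible effects of a corpus plus the per-trial exclusion log."""

    meta_id: str
    effects: tuple[EffectEstimate, ...]
    exclusions: tuple[tuple[str, str], ...]  # (trial_id, reason)
    method: SmdMethod = "hedges_g"

    def __len__(self) -> int:
        return len(self.effects)


def corpus_effects(
    corpus: Corpus,
    method: SmdMethod = "hedges_g",
    dropout_threshold: float = 0.10,
    n_source: Literal["randomized", "analyzed"] = "randomized",
) -> CorpusEffects:
    """Compute one direction-coded effect per admissible trial.

    A trial contributes iff its reporting status is ``reported_randomized``
    and both arms carry mean/sd summaries; every exclusion is logged with
    its reason.
    """
    effects: list[EffectEstimate] = []
    exclusions: list[tuple[str, str]] = []
    for trial in corpus:
        try:
            status = classify_reporting(trial, dropout_threshold)
        except ClassificationError as exc:
            exclusions.append((trial.trial_id, f"classification_error: {exc}"))
            continue
        if status.status is not ReportingCategory.REPORTED_RANDOMIZED:
            exclusions.append((trial.trial_id, status.status.value))
            continue
        try:
            smd, variance = raw_smd(trial.treatment, trial.control, method, n_source)
        except ValueError as exc:
            exclusions.append((trial.trial_id, f"smd_error: {exc}"))
            continue
        assert trial.orientation is not None  # enforced by TrialRecord invariant
        smd = orient_effect(smd, trial.orientation)
        if n_source == "analyzed":
            n_total = (trial.treatment.n_analyzed or 0) + (trial.control.n_analyzed or 0)
        else:
            n_total = trial.treatment.n_randomized + trial.control.n_randomized
        effects.append(EffectEstimate(trial.trial_id, smd, variance, n_total, method))
    return CorpusEffects(corpus.meta_id, tuple(effects), tuple(exclusions), method)
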
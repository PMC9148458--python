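"""Synthetic trial corpora with controlled randomization quality and missingness.

The generator emulates the data a meta-analyst extracts: per-trial arm
sizes, baseline means and SDs.  Trial i carries a true standardized
baseline difference

    delta_i = true_delta + tau * Z_i,   Z_i ~ N(0, 1),

which is identically zero under well-performed randomization
(``true_delta = 0, tau = 0``); ``true_delta != 0`` models a systematic
allocation failure ("subversion") and ``tau > 0`` trial-to-trial
variation in randomization quality.  Sample means are drawn from the
implied normal sampling distributions and sample SDs from the exact
scaled-chi law, so per-trial SMD sampling noise is realistic.

Non-reporting mechanisms then hide whole trials' baseline summaries
(the counts survive, the summaries become "not reported", exactly the
pattern seen in published trials):

* ``mcar`` — hide uniformly at random;
* ``mnar_magnitude`` — hide probability is a logistic function of the
  trial's own coded SMD (hide one direction preferentially);
* ``mnar_se`` — hide probability grows (or falls) with the trial's SE;
* ``subversion_masking`` — hide trials on the side *opposite* a
  systematic shift, so the observed effects stay displaced from zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import ArmSummary, BaselinePopulation, Corpus, Orientation, SummaryType, TrialRecord
from .diagnostics import ShapeThresholds, classify_shape, funnel_trend, guideline_curve, rank_percentiles
from .effects import corpus_effects, orient_effect, raw_smd
from .pooling import analyze_pooled

__all__ = [
    "MissingSpec",
    "SimConfig",
    "apply_missingness",
    "operating_characteristics",
    "simulate_corpus",
]

Mechanism = Literal["none", "mcar", "mnar_magnitude", "mnar_se", "subversion_masking"]


@dataclass(frozen=True)
class MissingSpec:
    """How baseline non-reporting is generated.

    ``p_base`` is the hide probability at a zero covariate (for
    ``subversion_masking`` it is the hide probability on the masked
    side); ``steepness`` scales how sharply the hide probability reacts
    to the SMD (per standardized unit) or to the SE (per SD of the SEs);
    ``direction`` names which sign of SMD is preferentially hidden.
    """

    mechanism: Mechanism = "none"
    p_base: float = 0.0
    steepness: float = 0.0
    direction: Literal["hide_positive", "hide_negative"] = "hide_positive"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_base <= 1.0:
            raise ValueError(f"p_base must lie in [0, 1], got {self.p_base}")
        if self.steepness < 0:
            raise ValueError("steepness must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for one synthetic meta-analysis corpus.

    ``n_per_arm`` is a sampling rule ``(name, *params)``: ``("fixed", n)``,
    ``("uniform", lo, hi)`` or ``("log_uniform", lo, hi)``.  The default
    log-uniform [10, 200] spans the arm sizes typical of the trials that
    feed systematic reviews.  ``outcome_sd`` is the common within-arm SD
    of the raw outcome (1 = already standardized).
    """

    k_trials: int = 20
    n_per_arm: tuple = ("log_uniform", 10, 200)
    true_delta: float = 0.0
    tau: float = 0.0
    outcome_sd: float = 1.0
    orientation: Orientation = Orientation.LOWER_IS_BETTER
    missingness: MissingSpec = field(default_factory=MissingSpec)
    seed: int = 0
    meta_id: str = "sim"

    def __post_init__(self) -> None:
        if self.k_trials < 1:
            raise ValueError("k_trials must be >= 1")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if not self.outcome_sd > 0:
            raise ValueError("outcome_sd must be > 0")


def _draw_arm_sizes(rule: tuple, k: int, rng: np.random.Generator) -> np.ndarray:
    name = rule[0]
    if name == "fixed":
        (n,) = rule[1:]
        if n < 2:
            raise ValueError("fixed arm size must be >= 2")
        return np.full(k, int(n))
    if name == "uniform":
        lo, hi = rule[1:]
    elif name == "log_uniform":
        lo, hi = rule[1:]
    else:
        raise ValueError(f"unknown arm-size rule {name!r}")
    if not 2 <= lo <= hi:
        raise ValueError(f"arm-size bounds must satisfy 2 <= lo <= hi, got {rule}")
    if name == "uniform":
        return rng.integers(lo, hi + 1, size=k)
    u = rng.uniform(math.log(lo), math.log(hi), size=k)
    return np.clip(np.rint(np.exp(u)).astype(int), lo, hi)


def simulate_corpus(config: SimConfig, rng: np.random.Generator | None = None) -> Corpus:
    """Generate one fully reported corpus of ``k_trials`` two-arm trials.

    Deterministic for a given ``(config, config.seed)``; pass ``rng`` to
    draw from an external stream instead.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    k = config.k_trials
    z = rng.standard_normal(k)
    delta = config.true_delta + config.tau * z
    n_t = _draw_arm_sizes(config.n_per_arm, k, rng)
    n_c = _draw_arm_sizes(config.n_per_arm, k, rng)
    # Direction coding flips the sign for higher-is-better outcomes, so
    # generate the raw mean difference with the sign that makes the
    # *coded* SMD target delta_i.
    sign = -1.0 if config.orientation is Orientation.HIGHER_IS_BETTER else 1.0
    sd = config.outcome_sd
    mu_t = sign * delta * sd
    mean_t = rng.normal(mu_t, sd / np.sqrt(n_t))
    mean_c = rng.normal(0.0, sd / np.sqrt(n_c))
    sd_t = sd * np.sqrt(rng.chisquare(n_t - 1) / (n_t - 1))
    sd_c = sd * np.sqrt(rng.chisquare(n_c - 1) / (n_c - 1))
    width = len(str(k))
    trials = tuple(
        TrialRecord(
            trial_id=f"t{i + 1:0{width}d}",
            meta_id=config.meta_id,
            treatment=ArmSummary(
                n_randomized=int(n_t[i]),
                n_analyzed=int(n_t[i]),
                mean=float(mean_t[i]),
                sd=float(sd_t[i]),
                summary_type=SummaryType.MEAN_SD,
            ),
            control=ArmSummary(
                n_randomized=int(n_c[i]),
                n_analyzed=int(n_c[i]),
                mean=float(mean_c[i]),
                sd=float(sd_c[i]),
                summary_type=SummaryType.MEAN_SD,
            ),
            baseline_population=BaselinePopulation.RANDOMIZED,
            orientation=config.orientation,
        )
        for i in range(k)
    )
    return Corpus(meta_id=config.meta_id, trials=trials)


def _logistic(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def _logit(p: float) -> float:
    if p <= 0.0:
        return -math.inf
    if p >= 1.0:
        return math.inf
    return math.log(p / (1.0 - p))


def _hide_arm(arm: ArmSummary) -> ArmSummary:
    return ArmSummary(
        n_randomized=arm.n_randomized,
        n_analyzed=arm.n_analyzed,
        summary_type=SummaryType.NONE,
    )


def apply_missingness(
    corpus: Corpus,
    spec: MissingSpec,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> Corpus:
    """Hide whole trials' baseline summaries per the missingness mechanism.

    Hidden trials keep their headcounts but both arms become
    ``summary_type=none`` (so they still feed reporting-rate statistics);
    retained trials are returned unmodified, bitwise.
    """
    if spec.mechanism == "none":
        return corpus
    if rng is None:
        rng = np.random.default_rng(seed)

    # coded SMD / SE per trial (None where not computable)
    smds: list[float | None] = []
    ses: list[float | None] = []
    for t in corpus:
        if (
            t.treatment.summary_type is SummaryType.MEAN_SD
            and t.control.summary_type is SummaryType.MEAN_SD
        ):
            d, v = raw_smd(t.treatment, t.control, "hedges_g")
            smds.append(orient_effect(d, t.orientation))
            ses.append(math.sqrt(v))
        else:
            smds.append(None)
            ses.append(None)

    known_se = [s for s in ses if s is not None]
    se_mean = float(np.mean(known_se)) if known_se else 0.0
    se_sd = float(np.std(known_se)) if len(known_se) > 1 else 0.0

    s = 1.0 if spec.direction == "hide_positive" else -1.0
    base = _logit(spec.p_base)
    new_trials = []
    for t, smd, se in zip(corpus.trials, smds, ses):
        if spec.mechanism == "mcar":
            p_hide = spec.p_base
        elif smd is None:
            p_hide = 0.0  # already unreported; nothing to hide
        elif spec.mechanism == "mnar_magnitude":
            p_hide = _logistic(base + spec.steepness * s * smd)
        elif spec.mechanism == "mnar_se":
            zse = (se - se_mean) / se_sd if se_sd > 0 else 0.0
            p_hide = _logistic(base + spec.steepness * zse)
        elif spec.mechanism == "subversion_masking":
            p_hide = spec.p_base if s * smd > 0 else 0.0
        else:
            raise ValueError(f"unknown mechanism {spec.mechanism!r}")
        if rng.uniform() < p_hide:
            t = replace(t, treatment=_hide_arm(t.treatment), control=_hide_arm(t.control))
        new_trials.append(t)
    return Corpus(meta_id=corpus.meta_id, trials=tuple(new_trials), label=corpus.label)


def _binom_se(p: float, n: int) -> float:
    return math.sqrt(max(p * (1.0 - p), 0.0) / n) if n > 0 else float("nan")

_SHAPE_LABELS = ("aligned", "shifted", "overdispersed", "skewed_right", "skewed_left")


def operating_characteristics(
    scenarios: Mapping[str, SimConfig],
    n_reps: int = 500,
    seed: int = 0,
    alpha_trend: float = 0.10,
    thresholds: ShapeThresholds | None = None,
) -> pd.DataFrame:
    """Monte-Carlo operating characteristics of the full diagnostic pipeline.

    Per scenario: rejection rate of the pooled-imbalance z-test at 0.05
    and 0.10, mean I^2, shape-label frequencies, and the funnel-trend
    detection rate at ``alpha_trend``, each with its Monte-Carlo SE.
    Fully determined by ``seed``; replicate r of scenario i draws from
    the spawn-key path (i, r).
    """
    root = np.random.SeedSequence(seed)
    rows = []
    for i, (name, cfg) in enumerate(scenarios.items()):
        scen_ss = np.random.SeedSequence(entropy=root.entropy, spawn_key=(i,))
        rej05 = rej10 = 0
        i2s: list[float] = []
        labels = {lab: 0 for lab in _SHAPE_LABELS}
        trend_hits = 0
        trend_n = 0
        shape_n = 0
        k_obs: list[int] = []
        for child in scen_ss.spawn(n_reps):
            rng = np.random.default_rng(child)
            corpus = simulate_corpus(cfg, rng=rng)
            corpus = apply_missingness(corpus, cfg.missingness, rng=rng)
            ce = corpus_effects(corpus)
            k_obs.append(len(ce))
            if len(ce) < 2:
                continue
            pooled = analyze_pooled(ce.effects)
            rej05 += pooled.p_pooled < 0.05
            rej10 += pooled.p_pooled < 0.10
            i2s.append(pooled.i2)
            ranked = rank_percentiles(ce.effects)
            curve = guideline_curve(pooled.var_b)
            shape = classify_shape(ranked, curve, thresholds)
            labels[shape.label] += 1
            shape_n += 1
            ses = [e.se for e in ce.effects]
            if len(ce) >= 3 and max(ses) > min(ses):
                trend = funnel_trend(ce.effects, alpha_trend=alpha_trend)
                trend_n += 1
                trend_hits += trend.direction != "none"
        m = shape_n
        row: dict[str, object] = {
            "scenario": name,
            "n_reps": n_reps,
            "n_analyzable": m,
            "mean_k_observed": float(np.mean(k_obs)),
            "reject_rate_05": rej05 / m if m else float("nan"),
            "mc_se_05": _binom_se(rej05 / m, m) if m else float("nan"),
            "reject_rate_10": rej10 / m if m else float("nan"),
            "mc_se_10": _binom_se(rej10 / m, m) if m else float("nan"),
            "mean_i2": float(np.mean(i2s)) if i2s else float("nan"),
            "mc_se_i2": float(np.std(i2s, ddof=1) / math.sqrt(len(i2s))) if len(i2s) > 1 else float("nan"),
            "trend_detect_rate": trend_hits / trend_n if trend_n else float("nan"),
            "mc_se_trend": _binom_se(trend_hits / trend_n, trend_n) if trend_n else float("nan"),
            "seed_path": f"({i}, 0..{n_reps - 1})",
        }
        for lab in _SHAPE_LABELS:
            p = labels[lab] / m if m else float("nan")
            row[f"frac_{lab}"] = p
            row[f"mc_se_{lab}"] = _binom_se(p, m) if m else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
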
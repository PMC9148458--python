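import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from baselinemeta.core import ArmSummary, Corpus, Orientation, SummaryType, TrialRecord
from baselinemeta.effects import EffectEstimate

settings.register_profile(
    "det", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("det")


def make_arm(n=50, mean=0.0, sd=1.0, n_analyzed=None, summary_type=SummaryType.MEAN_SD, **kw):
    if summary_type is SummaryType.MEAN_SD:
        return ArmSummary(n, n_analyzed, mean=mean, sd=sd, summary_type=summary_type, **kw)
    if summary_type is SummaryType.NONE:
        return ArmSummary(n, n_analyzed, summary_type=summary_type)
    return ArmSummary(n, n_analyzed, summary_type=summary_type, **kw)


def make_trial(trial_id="t1", meta_id="m1", orientation=Orientation.LOWER_IS_BETTER, **kw):
    defaults = dict(treatment=make_arm(), control=make_arm())
    defaults.update(kw)
    return TrialRecord(trial_id=trial_id, meta_id=meta_id, orientation=orientation, **defaults)


def random_effects(rng, k=None):
    """A random set of plausible effect estimates for property tests."""
    if k is None:
        k = int(rng.integers(2, 51))
    smds = rng.normal(0.0, 0.3, size=k)
    variances = rng.uniform(0.01, 0.25, size=k)
    return [
        EffectEstimate(f"t{i:03d}", float(smds[i]), float(variances[i]), n_total=100)
        for i in range(k)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def small_corpus():
    """Three complete mean/sd trials in one meta-analysis."""
    trials = tuple(
        make_trial(
            trial_id=f"t{i}",
            treatment=make_arm(mean=m_t, sd=1.2),
            control=make_arm(mean=0.0, sd=1.0),
        )
        for i, m_t in enumerate([-0.4, 0.1, 0.3], start=1)
    )
    return Corpus(meta_id="m1", trials=trials)


CSV_HEADER = (
    "meta_id,trial_id,orientation,baseline_population,"
    "n_rand_t,n_anal_t,mean_t,sd_t,median_t,iqr_low_t,iqr_high_t,summary_type_t,"
    "n_rand_c,n_anal_c,mean_c,sd_c,median_c,iqr_low_c,iqr_high_c,summary_type_c"
)


def csv_row(
    meta_id="m1",
    trial_id="t1",
    orientation="lower_is_better",
    population="randomized",
    n_rand=("50", "50"),
    n_anal=("", ""),
    mean=("0.1", "0.0"),
    sd=("1.0", "1.0"),
    median=("", ""),
    iqr=("", "", "", ""),
    summary_type=("mean_sd", "mean_sd"),
):
    return ",".join(
        [
            meta_id,
            trial_id,
            orientation,
            population,
            n_rand[0], n_anal[0], mean[0], sd[0], median[0], iqr[0], iqr[1], summary_type[0],
            n_rand[1], n_anal[1], mean[1], sd[1], median[1], iqr[2], iqr[3], summary_type[1],
        ]
    )


@pytest.fixture
def corpus_csv(tmp_path):
    """A 3-row, one-meta CSV file of complete mean/sd trials."""
    lines = [CSV_HEADER]
    for i, m in enumerate(["-0.2", "0.0", "0.3"], start=1):
        lines.append(csv_row(trial_id=f"t{i}", mean=(m, "0.0")))
    path = tmp_path / "corpus.csv"
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
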
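"""Reporting triage and SMD computation: worked examples and invariances."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from baselinemeta.core import (
    BaselinePopulation,
    Corpus,
    Orientation,
    ReportingCategory,
    SummaryType,
)
from baselinemeta.effects import (
    ClassificationError,
    classify_reporting,
    corpus_effects,
    orient_effect,
    raw_smd,
    reporting_rate,
)

from conftest import make_arm, make_trial


class TestClassifyReporting:
    def test_randomized_population_with_mean_sd(self):
        trial = make_trial(baseline_population=BaselinePopulation.RANDOMIZED)
        assert classify_reporting(trial).status is ReportingCategory.REPORTED_RANDOMIZED

    def test_low_dropout_admits_analyzed_only_trial(self):
        # 100+100 randomized, 92+92 analyzed: dropout (200-184)/200 = 0.08 < 0.10
        trial = make_trial(
            treatment=make_arm(n=100, n_analyzed=92),
            control=make_arm(n=100, n_analyzed=92),
            baseline_population=BaselinePopulation.ANALYZED_ONLY,
        )
        status = classify_reporting(trial)
        assert status.status is ReportingCategory.REPORTED_RANDOMIZED
        assert status.dropout_rate == pytest.approx(0.08)

    def test_high_dropout_flagged(self):
        trial = make_trial(
            treatment=make_arm(n=100, n_analyzed=85),
            control=make_arm(n=100, n_analyzed=85),
            baseline_population=BaselinePopulation.ANALYZED_ONLY,
        )
        assert classify_reporting(trial).status is ReportingCategory.REPORTED_ANALYZED_HIGH_DROPOUT

    def test_threshold_is_strict(self):
        trial = make_trial(
            treatment=make_arm(n=100, n_analyzed=90),
            control=make_arm(n=100, n_analyzed=90),
            baseline_population=BaselinePopulation.ANALYZED_ONLY,
        )
        # dropout exactly 0.10 is NOT below the threshold
        assert classify_reporting(trial).status is ReportingCategory.REPORTED_ANALYZED_HIGH_DROPOUT

    def test_median_iqr_excluded(self):
        trial = make_trial(
            treatment=make_arm(median=5.0, iqr_low=3.0, iqr_high=8.0, summary_type=SummaryType.MEDIAN_IQR),
            control=make_arm(),
        )
        assert classify_reporting(trial).status is ReportingCategory.REPORTED_MEDIAN_EXCLUDED

    def test_not_reported_takes_precedence(self):
        trial = make_trial(
            treatment=make_arm(summary_type=SummaryType.NONE),
            control=make_arm(median=5.0, iqr_low=3.0, iqr_high=8.0, summary_type=SummaryType.MEDIAN_IQR),
            orientation=None,
        )
        assert classify_reporting(trial).status is ReportingCategory.NOT_REPORTED

    def test_analyzed_only_without_counts_is_an_error(self):
        trial = make_trial(baseline_population=BaselinePopulation.ANALYZED_ONLY)
        with pytest.raises(ClassificationError):
            classify_reporting(trial)


class TestReportingRate:
    def _corpus(self):
        trials = (
            make_trial(trial_id="t1"),
            make_trial(trial_id="t2"),
            make_trial(
                trial_id="t3",
                treatment=make_arm(summary_type=SummaryType.NONE),
                control=make_arm(summary_type=SummaryType.NONE),
                orientation=None,
            ),
            make_trial(
                trial_id="t4",
                treatment=make_arm(median=5.0, iqr_low=3.0, iqr_high=8.0, summary_type=SummaryType.MEDIAN_IQR),
                control=make_arm(),
            ),
        )
        return Corpus(meta_id="m1", trials=trials)

    def test_counts_and_rate(self):
        rate, counts = reporting_rate(self._corpus())
        assert rate == 0.5
        assert counts == {
            "reported_randomized": 2,
            "reported_analyzed_high_dropout": 0,
            "reported_median_excluded": 1,
            "not_reported": 1,
        }
        assert sum(counts.values()) == 4

    def test_invariant_to_trial_order(self):
        corpus = self._corpus()
        shuffled = Corpus(meta_id="m1", trials=corpus.trials[::-1])
        assert reporting_rate(corpus)[1] == reporting_rate(shuffled)[1]


class TestRawSmd:
    def test_cohens_d_worked_example(self):
        a = make_arm(n=10, mean=1.0, sd=1.0)
        b = make_arm(n=10, mean=0.0, sd=1.0)
        d, v = raw_smd(a, b, "cohens_d")
        assert d == pytest.approx(1.0, abs=1e-12)
        assert v == pytest.approx(0.2 + 1.0 / 40.0, abs=1e-12)

    def test_hedges_g_worked_example(self):
        a = make_arm(n=10, mean=1.0, sd=1.0)
        b = make_arm(n=10, mean=0.0, sd=1.0)
        g, v = raw_smd(a, b, "hedges_g")
        assert g == pytest.approx(1.0 - 3.0 / 71.0, abs=1e-12)
        assert g == pytest.approx(0.957746, abs=1e-6)
        assert v == pytest.approx(0.2 + g * g / 40.0, abs=1e-12)
        assert v == pytest.approx(0.222932, abs=1e-6)

    def test_equal_means_give_zero(self):
        a = make_arm(n=14, mean=2.5, sd=0.7)
        b = make_arm(n=23, mean=2.5, sd=1.9)
        for method in ("cohens_d", "hedges_g"):
            assert raw_smd(a, b, method)[0] == 0.0

    def test_degenerate_scale_rejected(self):
        # sd=0 is rejected at the ArmSummary level already
        with pytest.raises(Exception, match="sd"):
            make_arm(n=10, mean=1.0, sd=0.0)

    def test_analyzed_counts_selectable(self):
        a = make_arm(n=100, n_analyzed=50, mean=1.0, sd=1.0)
        b = make_arm(n=100, n_analyzed=50, mean=0.0, sd=1.0)
        _, v_rand = raw_smd(a, b)
        _, v_anal = raw_smd(a, b, n_source="analyzed")
        assert v_anal > v_rand  # fewer heads, more variance

    @given(
        mean_t=st.floats(-5, 5),
        mean_c=st.floats(-5, 5),
        sd_t=st.floats(0.1, 5),
        sd_c=st.floats(0.1, 5),
        n_t=st.integers(2, 500),
        n_c=st.integers(2, 500),
        method=st.sampled_from(["cohens_d", "hedges_g"]),
    )
    def test_antisymmetry_under_arm_exchange(self, mean_t, mean_c, sd_t, sd_c, n_t, n_c, method):
        a = make_arm(n=n_t, mean=mean_t, sd=sd_t)
        b = make_arm(n=n_c, mean=mean_c, sd=sd_c)
        d_ab, v_ab = raw_smd(a, b, method)
        d_ba, v_ba = raw_smd(b, a, method)
        assert d_ab == pytest.approx(-d_ba, abs=1e-12)
        assert v_ab == pytest.approx(v_ba, abs=1e-12)

    @given(
        mean_t=st.floats(-5, 5),
        sd_t=st.floats(0.1, 5),
        n_t=st.integers(2, 500),
        c=st.floats(0.01, 100),
    )
    def test_scale_invariance(self, mean_t, sd_t, n_t, c):
        a = make_arm(n=n_t, mean=mean_t, sd=sd_t)
        b = make_arm(n=37, mean=0.3, sd=1.4)
        a2 = make_arm(n=n_t, mean=mean_t * c, sd=sd_t * c)
        b2 = make_arm(n=37, mean=0.3 * c, sd=1.4 * c)
        d1, _ = raw_smd(a, b)
        d2, _ = raw_smd(a2, b2)
        assert d2 == pytest.approx(d1, rel=1e-9, abs=1e-12)

    @given(
        mean_t=st.floats(-5, 5).filter(lambda x: abs(x - 0.3) > 1e-3),
        n=st.integers(2, 2000),
    )
    def test_hedges_shrinks_toward_zero(self, mean_t, n):
        a = make_arm(n=n, mean=mean_t, sd=1.0)
        b = make_arm(n=n, mean=0.3, sd=1.0)
        d, _ = raw_smd(a, b, "cohens_d")
        g, _ = raw_smd(a, b, "hedges_g")
        assert abs(g) < abs(d)
        assert g / d == pytest.approx(1.0, abs=3.0 / (4 * (2 * n - 2) - 1) + 1e-12)


class TestOrientEffect:
    def test_higher_is_better_flips_sign(self):
        assert orient_effect(0.3, Orientation.HIGHER_IS_BETTER) == -0.3

    def test_lower_is_better_is_identity(self):
        assert orient_effect(-0.2, Orientation.LOWER_IS_BETTER) == -0.2

    @given(st.floats(-10, 10))
    def test_double_flip_is_identity(self, x):
        assert orient_effect(orient_effect(x, "higher_is_better"), "higher_is_better") == x


class TestCorpusEffects:
    def test_bookkeeping_of_exclusions(self):
        trials = (
            make_trial(trial_id="t1"),
            make_trial(trial_id="t2"),
            make_trial(trial_id="t3", treatment=make_arm(mean=0.5)),
            make_trial(
                trial_id="t4",
                treatment=make_arm(summary_type=SummaryType.NONE),
                control=make_arm(summary_type=SummaryType.NONE),
                orientation=None,
            ),
            make_trial(
                trial_id="t5",
                treatment=make_arm(median=5.0, iqr_low=3.0, iqr_high=8.0, summary_type=SummaryType.MEDIAN_IQR),
                control=make_arm(),
            ),
        )
        ce = corpus_effects(Corpus(meta_id="m1", trials=trials))
        assert len(ce.effects) == 3
        assert dict(ce.exclusions) == {"t4": "not_reported", "t5": "reported_median_excluded"}

    def test_dropout_admitted_trial_contributes(self):
        trial = make_trial(
            treatment=make_arm(n=100, n_analyzed=95, mean=0.2),
            control=make_arm(n=100, n_analyzed=95),
            baseline_population=BaselinePopulation.ANALYZED_ONLY,
        )
        ce = corpus_effects(Corpus(meta_id="m1", trials=(trial,)))
        assert len(ce.effects) == 1

    def test_effect_invariants(self, small_corpus):
        for e in corpus_effects(small_corpus).effects:
            assert e.se == math.sqrt(e.variance)
            assert e.weight * e.variance == pytest.approx(1.0, abs=1e-15)
            assert e.variance > 0

    def test_orientation_applied(self):
        trial = make_trial(
            treatment=make_arm(mean=0.5),
            control=make_arm(mean=0.0),
            orientation=Orientation.HIGHER_IS_BETTER,
        )
        ce = corpus_effects(Corpus(meta_id="m1", trials=(trial,)))
        assert ce.effects[0].smd < 0
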
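"""GLIMMER score: dichotomization, scoring, classification, evaluation."""

import math

import numpy as np
import pytest

from glimmer.errors import DegenerateLabelsError, ValidationError
from glimmer.roc import auc_mann_whitney
from glimmer.score import (
    METHYLATED,
    UNMETHYLATED,
    ConfusionCounts,
    DiagnosticPerformance,
    ScoreDefinition,
    classify,
    derive_score_definition,
    dichotomize_mgmt,
    evaluate,
    glimmer_score,
    round_half_up,
)

DEFN = ScoreDefinition()


class TestDichotomizeMgmt:
    @pytest.mark.parametrize(
        "pct, expected",
        [
            (8.0, UNMETHYLATED),  # boundary inclusive for unmethylated
            (8.001, METHYLATED),
            (31.5, METHYLATED),
            (0.0, UNMETHYLATED),
            (100.0, METHYLATED),
        ],
    )
    def test_boundary_semantics(self, pct, expected):
        assert dichotomize_mgmt(pct, DEFN) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            dichotomize_mgmt(-1.0, DEFN)
        with pytest.raises(ValidationError):
            dichotomize_mgmt(101.0, DEFN)


class TestGlimmerScore:
    @pytest.mark.parametrize(
        "ohi, twi, expected",
        [
            (0.54, 0.72, 2),  # methylated-like illustrative pattern
            (0.75, 0.31, 0),  # unmethylated-like illustrative pattern
            (0.606, 0.501, 2),  # both boundaries inclusive
            (0.607, 0.501, 1),
            (0.606, 0.500, 1),
            (0.607, 0.500, 0),
        ],
    )
    def test_point_assignment(self, ohi, twi, expected):
        assert glimmer_score(ohi, twi, DEFN) == expected

    def test_monotone_in_both_indices(self, rng):
        ohi = rng.uniform(0, 1, 200)
        twi = rng.uniform(0, 1, 200)
        s = glimmer_score(ohi, twi, DEFN)
        s_better = glimmer_score(ohi - 0.05, twi + 0.05, DEFN)
        assert np.all(s_better >= s)

    def test_classification_rule(self):
        assert classify(1, DEFN) == METHYLATED
        assert classify(0, DEFN) == UNMETHYLATED
        strict = ScoreDefinition(positive_score_min=2)
        assert classify(2, strict) == METHYLATED
        assert classify(1, strict) == UNMETHYLATED

    def test_invalid_score_rejected(self):
        with pytest.raises(ValidationError):
            classify(3, DEFN)


class TestEvaluate:
    def test_published_confusion_metrics(self):
        predicted = [METHYLATED] * 18 + [UNMETHYLATED] + [METHYLATED] + [UNMETHYLATED] * 5
        truth = [METHYLATED] * 19 + [UNMETHYLATED] * 6
        perf = evaluate(predicted, truth)
        assert perf.counts == ConfusionCounts(tp=18, fp=1, tn=5, fn=1)
        disp = perf.display()
        assert disp["sensitivity_pct"] == 94.7
        assert disp["specificity_pct"] == 83.3
        assert disp["ppv_pct"] == 94.7
        assert disp["npv_pct"] == 83.3
        assert disp["accuracy_pct"] == 92.0
        assert disp["youden"] == 0.78

    def test_all_correct(self):
        truth = [METHYLATED, UNMETHYLATED, METHYLATED]
        perf = evaluate(truth, truth)
        assert perf.accuracy == 1.0
        assert perf.youden == 1.0

    def test_random_predictions_have_null_youden(self):
        rng = np.random.default_rng(123)
        n = 10_000
        truth = np.where(rng.random(n) < 0.5, METHYLATED, UNMETHYLATED)
        predicted = np.where(rng.random(n) < 0.5, METHYLATED, UNMETHYLATED)
        perf = evaluate(predicted, truth)
        assert abs(perf.youden) < 0.1

    def test_complement_classifier_flips_metrics(self, rng):
        n = 200
        truth = np.where(rng.random(n) < 0.6, METHYLATED, UNMETHYLATED)
        predicted = np.where(rng.random(n) < 0.5, METHYLATED, UNMETHYLATED)
        perf = evaluate(predicted, truth)
        flipped = np.where(predicted == METHYLATED, UNMETHYLATED, METHYLATED)
        perf_f = evaluate(flipped, truth)
        assert perf_f.sensitivity == pytest.approx(1.0 - perf.sensitivity)
        assert perf_f.specificity == pytest.approx(1.0 - perf.specificity)

    def test_permutation_invariance(self, rng):
        n = 60
        truth = np.where(rng.random(n) < 0.6, METHYLATED, UNMETHYLATED)
        predicted = np.where(rng.random(n) < 0.5, METHYLATED, UNMETHYLATED)
        perm = rng.permutation(n)
        a = evaluate(predicted, truth)
        b = evaluate(predicted[perm], truth[perm])
        assert a.counts == b.counts

    def test_zero_denominator_is_nan_not_zero(self):
        # no positive predictions -> PPV undefined
        perf = evaluate([UNMETHYLATED, UNMETHYLATED], [METHYLATED, UNMETHYLATED])
        assert math.isnan(perf.ppv)
        assert perf.npv == 0.5

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            evaluate([METHYLATED], [METHYLATED, UNMETHYLATED])


class TestRounding:
    @pytest.mark.parametrize(
        "value, ndigits, expected",
        [
            (93.75, 1, 93.8),  # half rounds up, not to even
            (94.736842, 1, 94.7),
            (83.333333, 1, 83.3),
            (0.78499, 2, 0.78),
            (0.775, 2, 0.78),
        ],
    )
    def test_half_up(self, value, ndigits, expected):
        assert round_half_up(value, ndigits) == expected


class TestScoreOnFixture:
    def test_fixture_confusion_overall(self, fixture_cohort):
        scores = glimmer_score(
            fixture_cohort["ohi"].to_numpy(), fixture_cohort["twi"].to_numpy(), DEFN
        )
        predicted = classify(scores, DEFN)
        perf = evaluate(predicted, fixture_cohort["mgmt_status"].to_numpy())
        assert perf.counts == ConfusionCounts(tp=18, fp=1, tn=5, fn=1)

    def test_fixture_subgroup_confusion(self, fixture_cohort):
        sub = fixture_cohort[
            (fixture_cohort["idh_status"] == "wildtype") & (fixture_cohort["who_grade"] == 4)
        ]
        scores = glimmer_score(sub["ohi"].to_numpy(), sub["twi"].to_numpy(), DEFN)
        perf = evaluate(classify(scores, DEFN), sub["mgmt_status"].to_numpy())
        assert perf.counts == ConfusionCounts(tp=12, fp=1, tn=3, fn=0)

    def test_three_level_score_auc_is_108_of_114(self, fixture_cohort):
        scores = glimmer_score(
            fixture_cohort["ohi"].to_numpy(), fixture_cohort["twi"].to_numpy(), DEFN
        )
        truth = (fixture_cohort["mgmt_status"] == METHYLATED).to_numpy()
        auc = auc_mann_whitney(scores, truth, "higher_positive")
        # enumerate all 19 x 6 pairs by brute force
        pos = scores[truth]
        neg = scores[~truth]
        wins = ties = 0
        for p in pos:
            for q in neg:
                if p > q:
                    wins += 1
                elif p == q:
                    ties += 1
        assert wins + 0.5 * ties == 108.0
        assert auc == pytest.approx(108 / 114, abs=1e-15)


class TestDeriveScoreDefinition:
    def test_perfect_separation_recovers_boundary(self):
        # OHI separates below 0.5: largest methylated value is the cut-off
        ohi = np.array([0.30, 0.35, 0.42, 0.70, 0.80])
        twi = np.array([0.9, 0.8, 0.85, 0.2, 0.1])
        truth = [METHYLATED] * 3 + [UNMETHYLATED] * 2
        defn = derive_score_definition(ohi, twi, truth)
        assert defn.ohi_cutoff == 0.42
        assert defn.twi_cutoff == 0.8  # smallest methylated TWI

    def test_fixture_cutoffs_separate_observed_value_bands(self, fixture_cohort):
        # by construction the fixture's methylated OHI values all sit below
        # every unmethylated value, so the derived cut-off is the largest
        # methylated OHI; the TWI cut-off lands on the smallest
        # methylated TWI-positive value
        defn = derive_score_definition(
            fixture_cohort["ohi"].to_numpy(),
            fixture_cohort["twi"].to_numpy(),
            fixture_cohort["mgmt_status"].to_numpy(),
        )
        meth = fixture_cohort["mgmt_status"] == METHYLATED
        assert defn.ohi_cutoff == fixture_cohort.loc[meth, "ohi"].max()
        assert (fixture_cohort.loc[~meth, "ohi"] > defn.ohi_cutoff).all()
        assert 0.501 <= defn.twi_cutoff <= 0.719

    def test_single_class_raises(self):
        with pytest.raises(DegenerateLabelsError):
            derive_score_definition([0.5, 0.6], [0.5, 0.6], [METHYLATED, METHYLATED])
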
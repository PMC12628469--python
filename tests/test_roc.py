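"""ROC machinery: AUC with ties, DeLong variance, Youden cut-offs, bootstrap."""

import numpy as np
import pytest

from glimmer.errors import DegenerateLabelsError, EmptyInputError, ValidationError
from glimmer.roc import (
    auc_mann_whitney,
    bootstrap_auc_ci,
    delong_ci,
    roc_points,
    youden_optimal,
)

from _oracles import trapezoid_auc


class TestAUC:
    def test_perfect_separation(self):
        marker = np.array([0.9, 0.8, 0.7, 0.2, 0.1])
        label = np.array([1, 1, 1, 0, 0], dtype=bool)
        assert roc_points(marker, label, "higher_positive").auc == 1.0

    def test_all_tied_marker(self):
        marker = np.ones(6)
        label = np.array([1, 1, 1, 0, 0, 0], dtype=bool)
        assert roc_points(marker, label, "higher_positive").auc == 0.5

    def test_enumerated_pair_example(self):
        # positives 0.9 and 0.4 vs negative 0.6: one win, one loss
        auc = auc_mann_whitney([0.9, 0.4, 0.6], [True, True, False], "higher_positive")
        assert auc == 0.5

    def test_direction_reversal_complements_auc(self, rng):
        marker = rng.normal(size=40)
        label = rng.random(40) < 0.5
        label[0], label[1] = True, False
        a = auc_mann_whitney(marker, label, "higher_positive")
        b = auc_mann_whitney(marker, label, "lower_positive")
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_rank_invariance_under_affine_maps(self, rng):
        marker = rng.normal(size=30)
        label = np.concatenate([np.ones(15, bool), np.zeros(15, bool)])
        base = roc_points(marker, label, "higher_positive")
        shifted = roc_points(marker + 5.0, label, "higher_positive")
        scaled = roc_points(marker * 3.0, label, "higher_positive")
        for other in (shifted, scaled):
            assert other.auc == pytest.approx(base.auc, abs=1e-12)
            assert np.allclose(other.sens, base.sens)
            assert np.allclose(other.spec, base.spec)

    def test_trapezoid_equals_mann_whitney(self, rng):
        for _ in range(200):
            n_pos = rng.integers(2, 15)
            n_neg = rng.integers(2, 15)
            # coarse grid forces ties
            marker = rng.integers(0, 6, n_pos + n_neg).astype(float)
            label = np.concatenate([np.ones(n_pos, bool), np.zeros(n_neg, bool)])
            direction = "higher_positive" if rng.random() < 0.5 else "lower_positive"
            r = roc_points(marker, label, direction)
            assert r.auc == pytest.approx(trapezoid_auc(r), abs=1e-12)

    def test_monotone_sweep(self, rng):
        marker = rng.normal(size=30)
        label = np.concatenate([np.ones(12, bool), np.zeros(18, bool)])
        r = roc_points(marker, label, "higher_positive")
        # as the threshold rises, the higher-positive rule tightens
        assert np.all(np.diff(r.sens) <= 1e-12)
        assert np.all(np.diff(r.spec) >= -1e-12)

    def test_degenerate_labels_raise(self):
        with pytest.raises(DegenerateLabelsError):
            roc_points([1.0, 2.0], [True, True], "higher_positive")
        with pytest.raises(EmptyInputError):
            roc_points([], [], "higher_positive")


class TestDeLong:
    def test_perfect_separation_zero_width(self):
        marker = np.array([3.0, 2.5, 2.0, 1.0, 0.5])
        label = np.array([1, 1, 1, 0, 0], dtype=bool)
        res = delong_ci(marker, label, "higher_positive")
        assert res.variance == 0.0
        assert res.ci == (1.0, 1.0)

    def test_matches_hand_computed_placements(self):
        # 3 positives (4, 2, 3), 2 negatives (1, 3); higher_positive
        marker = np.array([4.0, 2.0, 3.0, 1.0, 3.0])
        label = np.array([1, 1, 1, 0, 0], dtype=bool)
        # placements of positives vs negatives {1, 3}:
        #   4 -> (1 + 1)/2 = 1.0 ; 2 -> (1 + 0)/2 = 0.5 ; 3 -> (1 + 0.5)/2 = 0.75
        # placements of negatives, oriented toward the positive class
        # (V01_j = mean_i [x_i > y_j] + 0.5 [x_i = y_j]):
        #   y=1 -> (1 + 1 + 1)/3 = 1.0 ; y=3 -> (1 + 0 + 0.5)/3 = 0.5
        v_pos = np.array([1.0, 0.5, 0.75])
        v_neg = np.array([1.0, 0.5])
        expected_auc = v_pos.mean()
        expected_var = np.var(v_pos, ddof=1) / 3 + np.var(v_neg, ddof=1) / 2
        res = delong_ci(marker, label, "higher_positive")
        assert res.auc == pytest.approx(expected_auc, abs=1e-12)
        assert res.variance == pytest.approx(expected_var, abs=1e-12)

    def test_ci_endpoints_clipped(self, rng):
        for _ in range(20):
            marker = rng.normal(size=10)
            label = np.concatenate([np.ones(5, bool), np.zeros(5, bool)])
            res = delong_ci(marker, label, "higher_positive")
            assert 0.0 <= res.ci[0] <= res.auc <= res.ci[1] <= 1.0

    def test_width_agrees_with_bootstrap(self, rng):
        # moderately informative marker, 40 cases per class
        pos = rng.normal(0.7, 1.0, 40)
        neg = rng.normal(0.0, 1.0, 40)
        marker = np.concatenate([pos, neg])
        label = np.concatenate([np.ones(40, bool), np.zeros(40, bool)])
        dl = delong_ci(marker, label, "higher_positive")
        bs = bootstrap_auc_ci(marker, label, "higher_positive", n_boot=2000, seed=12)
        w_dl = dl.ci[1] - dl.ci[0]
        w_bs = bs[1] - bs[0]
        assert abs(w_dl - w_bs) / w_bs < 0.2

    def test_small_class_raises(self):
        with pytest.raises(ValidationError):
            delong_ci([1.0, 2.0, 3.0], [True, False, False], "higher_positive")


class TestYouden:
    def test_perfect_separation_reaches_one(self):
        marker = np.array([0.9, 0.8, 0.2, 0.1])
        label = np.array([1, 1, 0, 0], dtype=bool)
        op = youden_optimal(roc_points(marker, label, "higher_positive"))
        assert op.youden == pytest.approx(1.0)
        assert op.sens == 1.0 and op.spec == 1.0

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(200):
            n = rng.integers(6, 30)
            marker = rng.integers(0, 8, n).astype(float)
            label = rng.random(n) < 0.5
            label[0], label[1] = True, False
            for direction in ("higher_positive", "lower_positive"):
                r = roc_points(marker, label, direction)
                op = youden_optimal(r)
                pos = marker[label]
                neg = marker[~label]
                best = -np.inf
                for t in np.unique(marker):
                    if direction == "lower_positive":
                        j = (pos <= t).mean() + (neg > t).mean() - 1.0
                    else:
                        j = (pos >= t).mean() + (neg < t).mean() - 1.0
                    best = max(best, j)
                assert op.youden == pytest.approx(best, abs=1e-12)

    def test_specificity_breaks_ties(self):
        # two thresholds share J = 0.5; the higher-specificity one must win.
        # higher_positive on marker {1: neg, 2: pos, 3: neg, 4: pos}:
        #   t=2: sens 1.0, spec 0.5, J 0.5 ; t=4: sens 0.5, spec 1.0, J 0.5
        marker = np.array([1.0, 2.0, 3.0, 4.0])
        label = np.array([0, 1, 0, 1], dtype=bool)
        op = youden_optimal(roc_points(marker, label, "higher_positive"))
        assert op.spec == 1.0
        assert op.threshold == 4.0


class TestBootstrap:
    def test_perfect_separation(self):
        marker = np.array([5.0, 4.0, 1.0, 0.0])
        label = np.array([1, 1, 0, 0], dtype=bool)
        assert bootstrap_auc_ci(marker, label, "higher_positive", seed=0) == (1.0, 1.0)

    def test_deterministic_given_seed(self, rng):
        marker = rng.normal(size=30)
        label = np.concatenate([np.ones(15, bool), np.zeros(15, bool)])
        a = bootstrap_auc_ci(marker, label, "higher_positive", n_boot=500, seed=5)
        b = bootstrap_auc_ci(marker, label, "higher_positive", n_boot=500, seed=5)
        assert a == b

    def test_covers_true_auc(self):
        # binormal configuration with AUC = Phi(mu/sqrt(2)) = 0.75
        from scipy.stats import norm

        mu = np.sqrt(2) * norm.ppf(0.75)
        rng = np.random.default_rng(77)
        pos = rng.normal(mu, 1.0, 400)
        neg = rng.normal(0.0, 1.0, 400)
        marker = np.concatenate([pos, neg])
        label = np.concatenate([np.ones(400, bool), np.zeros(400, bool)])
        lo, hi = bootstrap_auc_ci(marker, label, "higher_positive", n_boot=500, seed=3)
        assert lo <= 0.75 <= hi

    def test_too_few_resamples_rejected(self):
        with pytest.raises(ValidationError):
            bootstrap_auc_ci([1.0, 0.0], [True, False], n_boot=10)


class TestCrossCheck:
    def test_against_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(25):
            n = rng.integers(10, 60)
            marker = rng.normal(size=n) + rng.integers(0, 3, n)
            label = rng.random(n) < 0.4
            label[0], label[1] = True, False
            ours = auc_mann_whitney(marker, label, "higher_positive")
            ref = roc_auc_score(label, marker)
            assert ours == pytest.approx(ref, abs=1e-12)
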
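import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acidostab.scoring import (
    SCORING_FEATURES,
    EvaluationResult,
    HillClimbScorer,
    delta_matrix,
    evaluate_cross_pairs,
    evaluate_ortholog_pairs,
    hill_climb,
    published_weights,
    relative_difference,
    roc_auc,
    roc_points,
    score_pair,
)
from acidostab.synthetic import generate_separable_deltas


def vec(**kwargs):
    base = {name: 0.0 for name in SCORING_FEATURES}
    base.update(kwargs)
    return base


class TestRelativeDifference:
    def test_both_zero_convention(self):
        d = relative_difference(vec(), vec())
        assert all(v == 0.0 for v in d.values())

    def test_symmetric_mode_hand_value(self):
        d = relative_difference(vec(x_K=0.06), vec(x_K=0.04))
        assert d["x_K"] == pytest.approx(0.2)

    def test_swap_negates(self):
        f1, f2 = vec(x_K=0.06, x_T=0.01), vec(x_K=0.04, x_T=0.05)
        d12 = relative_difference(f1, f2)
        d21 = relative_difference(f2, f1)
        for name in SCORING_FEATURES:
            assert d12[name] == pytest.approx(-d21[name])

    def test_missing_feature_rejected(self):
        with pytest.raises(ValueError):
            relative_difference({"x_K": 1.0}, {"x_K": 1.0})

    def test_alternative_modes(self):
        f1, f2 = vec(x_K=0.06), vec(x_K=0.04)
        assert relative_difference(f1, f2, mode="plain")["x_K"] == pytest.approx(0.02)
        assert relative_difference(f1, f2, mode="reference")["x_K"] == pytest.approx(0.5)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        x1=st.floats(0, 1, allow_nan=False),
        x2=st.floats(0, 1, allow_nan=False),
    )
    def test_symmetric_mode_bounded(self, x1, x2):
        d = relative_difference(vec(x_K=x1), vec(x_K=x2))["x_K"]
        assert -1.0 <= d <= 1.0


class TestScorePair:
    def test_zero_deltas_zero_score(self):
        assert score_pair(vec(), published_weights()) == 0.0

    def test_single_feature_published_weight(self):
        assert score_pair(vec(x_T=1.0), published_weights()) == pytest.approx(0.90)

    def test_two_feature_hand_arithmetic(self):
        s = score_pair(vec(x_K=0.5, x_Y=0.5), published_weights())
        assert s == pytest.approx(0.68 * 0.5 - 0.53 * 0.5)

    def test_published_weights_within_unit_box(self):
        w = published_weights()
        assert list(w) == list(SCORING_FEATURES)
        assert all(abs(v) <= 1 for v in w.values())

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(row=st.lists(st.floats(-1, 1, allow_nan=False), min_size=10, max_size=10))
    def test_score_antisymmetry(self, row):
        w = published_weights()
        d_fwd = dict(zip(SCORING_FEATURES, row))
        d_rev = dict(zip(SCORING_FEATURES, (-v for v in row)))
        assert score_pair(d_fwd, w) == pytest.approx(-score_pair(d_rev, w), abs=1e-12)


class TestHillClimb:
    def test_accepted_objective_monotone(self):
        X, _ = generate_separable_deltas(100, margin=0.3, noise_sd=0.2, seed=0)
        _, traces = hill_climb(X, iterations=2000, seed=1, restarts=2)
        for trace in traces:
            assert trace == sorted(trace)

    def test_single_informative_feature_solved(self):
        # every oriented pair has delta +1 on x_T only: any positive w_T wins
        X = np.zeros((50, 10))
        X[:, SCORING_FEATURES.index("x_T")] = 1.0
        w, _ = hill_climb(X, iterations=2000, seed=0, restarts=3)
        assert np.count_nonzero(X @ w > 0) == 50

    def test_deterministic_under_seed(self):
        X, _ = generate_separable_deltas(50, margin=0.3, seed=3)
        w1, _ = hill_climb(X, iterations=500, seed=7)
        w2, _ = hill_climb(X, iterations=500, seed=7)
        assert np.array_equal(w1, w2)

    def test_weights_clamped(self):
        X, _ = generate_separable_deltas(50, margin=0.3, seed=4)
        w, _ = hill_climb(X, iterations=2000, seed=5)
        assert np.all(np.abs(w) <= 1.0)

    def test_invalid_iterations(self):
        with pytest.raises(ValueError):
            hill_climb(np.ones((5, 10)), iterations=0)

    def test_estimator_fit_predict(self):
        X, _ = generate_separable_deltas(80, margin=1.0, seed=6)
        y = np.ones(80)
        y[40:] = -1
        X_oriented = X * y[:, None]  # reverse half the pairs
        model = HillClimbScorer(iterations=30000, restarts=5, seed=0).fit(X_oriented, y)
        acc = (model.predict(X_oriented) == y).mean()
        assert acc >= 0.9
        assert model.get_params()["iterations"] == 30000


class TestEvaluation:
    def test_accuracy_arithmetic(self):
        res = EvaluationResult(tp=3, tn=1, fp=0, fn=1, auc=0.5)
        assert res.accuracy == pytest.approx(0.8)

    def test_all_positive_scores(self):
        X = np.ones((10, 10)) * 0.1
        res = evaluate_ortholog_pairs(X, np.ones(10))
        assert res.accuracy == 1.0
        assert res.tp == res.tn == 10

    def test_zero_score_counts_incorrect(self):
        X = np.zeros((4, 10))
        res = evaluate_ortholog_pairs(X, np.ones(10))
        assert res.tp == 0
        assert res.accuracy == 0.0

    def test_cross_pairs_cardinality(self):
        w = published_weights()
        ap = [dict(zip(SCORING_FEATURES, np.random.default_rng(i).uniform(0, 1, 10))) for i in range(3)]
        np_ = [dict(zip(SCORING_FEATURES, np.random.default_rng(10 + i).uniform(0, 1, 10))) for i in range(4)]
        res = evaluate_cross_pairs(ap, np_, w)
        assert res.tp + res.fn == 12

    def test_cross_pairs_single_positive(self):
        w = published_weights()
        ap = [dict(zip(SCORING_FEATURES, [0.5, 0.5, 0.5, 0.5, 0, 0, 0, 0, 0, 0]))]
        np_ = [dict(zip(SCORING_FEATURES, [0.1, 0.1, 0.1, 0.1, 0, 0, 0, 0, 0, 0]))]
        res = evaluate_cross_pairs(ap, np_, w)
        assert res.accuracy == 1.0

    def test_cross_pairs_zero_weights(self):
        w = {name: 0.0 for name in SCORING_FEATURES}
        ap = [dict(zip(SCORING_FEATURES, np.ones(10)))]
        np_ = [dict(zip(SCORING_FEATURES, np.zeros(10)))]
        assert evaluate_cross_pairs(ap, np_, w).accuracy == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            evaluate_cross_pairs([], [vec()], published_weights())


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8], [0.1, 0.2]) == 1.0

    def test_half_wins(self):
        assert roc_auc([0.8, 0.2], [0.6, 0.4]) == pytest.approx(0.5)

    def test_all_ties(self):
        assert roc_auc([0.5], [0.5]) == pytest.approx(0.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([], [0.5])

    def test_matches_trapezoidal_area(self):
        rng = np.random.default_rng(0)
        pos = list(rng.normal(0.6, 0.3, 50))
        neg = list(rng.normal(0.4, 0.3, 60))
        pts = roc_points(pos, neg)
        xs, ys = zip(*pts)
        trapezoid = float(np.trapezoid(ys, xs))
        assert roc_auc(pos, neg) == pytest.approx(trapezoid, abs=1e-12)

    def test_matches_trapezoid_with_ties(self):
        pos = [0.5, 0.5, 0.7, 0.1]
        neg = [0.5, 0.3, 0.3, 0.9]
        pts = roc_points(pos, neg)
        xs, ys = zip(*pts)
        assert roc_auc(pos, neg) == pytest.approx(float(np.trapezoid(ys, xs)), abs=1e-12)


class TestDeltaMatrix:
    def test_matches_relative_difference(self):
        rng = np.random.default_rng(0)
        f1 = dict(zip(SCORING_FEATURES, rng.uniform(0, 0.2, 10)))
        f2 = dict(zip(SCORING_FEATURES, rng.uniform(0, 0.2, 10)))
        X = delta_matrix([(f1, f2)])
        d = relative_difference(f1, f2)
        assert np.allclose(X[0], [d[n] for n in SCORING_FEATURES])
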
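"""Soft-margin linear SVM: optimality, feasibility, and score conventions."""

import numpy as np
import pytest

from wedag.svm import (
    DegenerateDataError,
    decision_score,
    model_from_dict,
    model_to_dict,
    predict,
    primal_objective,
    train_svm,
)

from conftest import svm_dual_optimum


def grid_objective_1d(x, y_num, penalty, w_range=(-4, 4), b_range=(-4, 4)):
    """Coarse-to-fine grid search over the two-parameter 1D primal."""
    w_lo, w_hi = w_range
    b_lo, b_hi = b_range
    best = np.inf
    for _ in range(4):
        ws = np.linspace(w_lo, w_hi, 201)
        bs = np.linspace(b_lo, b_hi, 201)
        W, B = np.meshgrid(ws, bs, indexing="ij")
        margins = y_num[None, None, :] * (W[..., None] * x[None, None, :] - B[..., None])
        obj = 0.5 * W**2 + penalty * np.maximum(0.0, 1.0 - margins).sum(axis=-1)
        i, j = np.unravel_index(np.argmin(obj), obj.shape)
        best = obj[i, j]
        dw, db = ws[1] - ws[0], bs[1] - bs[0]
        w_lo, w_hi = ws[i] - 2 * dw, ws[i] + 2 * dw
        b_lo, b_hi = bs[j] - 2 * db, bs[j] + 2 * db
    return best


class TestTrainSVM:
    def test_two_point_hard_margin_solution(self):
        # x = -1 (y=-1), x = +1 (y=+1): the max-margin hyperplane is w=1, b=0
        model = train_svm(np.array([[-1.0], [1.0]]), [-1, 1], penalty=1000.0,
                          pos_class=1, neg_class=-1)
        assert model.w[0] == pytest.approx(1.0, abs=1e-6)
        assert model.b == pytest.approx(0.0, abs=1e-6)
        assert model.slack.max() < 1e-6

    def test_separable_data_has_vanishing_slack(self, rng):
        X = np.vstack([rng.normal(-3, 0.3, size=(10, 2)),
                       rng.normal(3, 0.3, size=(10, 2))])
        y = np.array(["a"] * 10 + ["b"] * 10)
        model = train_svm(X, y, penalty=100.0)
        assert model.slack.max() < 1e-6

    def test_non_separable_1d_matches_grid_oracle(self):
        x = np.array([-1.0, 1.0, -2.0, 2.0])
        y_num = np.array([1.0, -1.0, -1.0, 1.0])
        for penalty in (0.05, 1.0):
            model = train_svm(x[:, None], y_num, penalty=penalty,
                              pos_class=1.0, neg_class=-1.0)
            achieved = primal_objective(model, x[:, None], y_num)
            oracle = grid_objective_1d(x, y_num, penalty)
            assert achieved == pytest.approx(oracle, abs=1e-3)

    def test_feasibility_of_trained_constraints(self, rng):
        X = rng.normal(size=(12, 3))
        y = rng.choice(["p", "q"], size=12)
        y[:2] = ["p", "q"]
        model = train_svm(X, y, penalty=0.5)
        y_num = np.where(y == model.pos_class, 1.0, -1.0)
        assert np.all(model.slack >= 0)
        assert np.all(y_num * (X @ model.w - model.b) >= 1 - model.slack - 1e-8)

    def test_objective_matches_dual_oracle_on_random_sets(self, rng):
        for trial in range(20):
            n = int(rng.integers(4, 13))
            X = rng.normal(size=(n, 2))
            y_num = rng.choice([-1.0, 1.0], size=n)
            y_num[:2] = [-1.0, 1.0]
            penalty = float(rng.choice([0.05, 0.5, 5.0]))
            model = train_svm(X, y_num, penalty=penalty,
                              pos_class=1.0, neg_class=-1.0)
            achieved = primal_objective(model, X, y_num)
            optimum = svm_dual_optimum(X, y_num, penalty)
            assert abs(achieved - optimum) <= 1e-6 * max(1.0, abs(optimum)), trial

    def test_label_swap_negates_hyperplane_and_scores(self, rng):
        X = rng.normal(size=(10, 2))
        y = np.array(["a"] * 5 + ["b"] * 5)
        m1 = train_svm(X, y, penalty=0.3, pos_class="a", neg_class="b")
        m2 = train_svm(X, y, penalty=0.3, pos_class="b", neg_class="a")
        np.testing.assert_allclose(m1.w, -m2.w, atol=1e-6)
        assert m1.b == pytest.approx(-m2.b, abs=1e-6)
        x = rng.normal(size=2)
        assert decision_score(m1, x) == pytest.approx(-decision_score(m2, x), abs=1e-6)

    def test_increasing_penalty_never_raises_training_error_when_separable(self, rng):
        X = np.vstack([rng.normal(-2, 0.4, size=(12, 2)),
                       rng.normal(2, 0.4, size=(12, 2))])
        y = np.array([-1] * 12 + [1] * 12)
        errors = []
        for penalty in (0.01, 0.1, 1.0, 10.0):
            model = train_svm(X, y, penalty=penalty, pos_class=1, neg_class=-1)
            errors.append(int(np.sum(predict(model, X) != y)))
        assert all(a >= b for a, b in zip(errors, errors[1:]))

    def test_degenerate_and_invalid_inputs(self):
        X = np.zeros((3, 2))
        with pytest.raises(DegenerateDataError):
            train_svm(X, ["a", "a", "a"])
        with pytest.raises(ValueError):
            train_svm(X, ["a", "b", "c"])
        with pytest.raises(ValueError):
            train_svm(X, ["a", "b", "a"], penalty=0.0)

    def test_determinism(self, rng):
        X = rng.normal(size=(14, 3))
        y = rng.choice([0, 1], size=14)
        y[:2] = [0, 1]
        m1 = train_svm(X, y, penalty=0.05, pos_class=1, neg_class=0)
        m2 = train_svm(X.copy(), y.copy(), penalty=0.05, pos_class=1, neg_class=0)
        np.testing.assert_array_equal(m1.w, m2.w)
        assert m1.b == m2.b


class TestDecisionScore:
    def test_direct_evaluation(self):
        model = train_svm(np.array([[-1.0], [1.0]]), [-1, 1], penalty=1000.0,
                          pos_class=1, neg_class=-1)
        assert decision_score(model, np.array([0.5])) == pytest.approx(0.5, abs=1e-6)

    def test_margin_points_score_plus_minus_one(self):
        model = train_svm(np.array([[-1.0], [1.0]]), [-1, 1], penalty=1000.0,
                          pos_class=1, neg_class=-1)
        assert abs(decision_score(model, np.array([1.0]))) == pytest.approx(1.0, abs=1e-6)
        assert abs(decision_score(model, np.array([-1.0]))) == pytest.approx(1.0, abs=1e-6)

    def test_reflection_through_hyperplane_negates_score(self, rng):
        X = rng.normal(size=(10, 3))
        y = np.array([-1] * 5 + [1] * 5)
        model = train_svm(X, y, penalty=0.7, pos_class=1, neg_class=-1)
        x = rng.normal(size=3)
        s = decision_score(model, x)
        x_reflected = x - 2 * s * model.w / (model.w @ model.w)
        assert decision_score(model, x_reflected) == pytest.approx(-s, abs=1e-9)

    def test_dimension_mismatch_rejected(self):
        model = train_svm(np.array([[-1.0], [1.0]]), [-1, 1], penalty=1.0,
                          pos_class=1, neg_class=-1)
        with pytest.raises(ValueError):
            decision_score(model, np.zeros(3))

    def test_sign_zero_breaks_toward_pos_class(self):
        from wedag.svm import BinarySVMModel

        model = BinarySVMModel(w=np.array([1.0]), b=0.0, penalty=1.0,
                               pos_class="pos", neg_class="neg")
        assert predict(model, np.array([0.0])) == "pos"

    def test_json_round_trip_preserves_scores(self, rng):
        X = rng.normal(size=(8, 2))
        y = np.array(["u"] * 4 + ["v"] * 4)
        model = train_svm(X, y, penalty=0.05)
        restored = model_from_dict(model_to_dict(model))
        x = rng.normal(size=2)
        assert decision_score(restored, x) == decision_score(model, x)
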
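import numpy as np
import pytest

from pdpattern.svm import (
    classify,
    decision_value,
    dual_objective,
    grid_search_nested_cv,
    max_kkt_violation,
    train_svc,
    train_svr,
)

from _oracles import qp_svc, qp_svr

TIGHT = dict(tol=1e-8)


def random_svc_instance(rng, separable=False):
    n = int(rng.integers(6, 21))
    k = int(rng.integers(2, 6))
    X = rng.normal(size=(n, k))
    if separable:
        t = np.where(X[:, 0] > 0, 1.0, -1.0)
        X[:, 0] += 2.0 * t
    else:
        t = rng.choice([-1.0, 1.0], size=n)
    if np.unique(t).size < 2:
        t[0] = -t[0]
    return X, t


class TestSVC:
    def test_symmetric_pair_maximum_margin(self):
        X = np.array([[-1.0], [1.0]])
        t = np.array([-1.0, 1.0])
        m = train_svc(X, t, C=1e6, **TIGHT)
        assert m.w[0] == pytest.approx(1.0, abs=1e-6)
        assert m.b == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("separable", [True, False])
    @pytest.mark.parametrize("C", [0.1, 1.0, 100.0])
    def test_matches_qp_oracle(self, separable, C):
        rng = np.random.default_rng(hash((separable, C)) % 2**31)
        for _ in range(5):
            X, t = random_svc_instance(rng, separable)
            m = train_svc(X, t, C=C, **TIGHT)
            _, w_qp, obj_qp = qp_svc(X, t, C)
            assert dual_objective(m) == pytest.approx(obj_qp, abs=1e-6)
            np.testing.assert_allclose(m.w, w_qp, atol=1e-4)
            assert max_kkt_violation(m) < 1e-7

    def test_small_C_all_alphas_within_box_and_small_gap(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(12, 2))
        t = np.concatenate([np.ones(6), -np.ones(6)])  # overlapping classes
        C = 0.05
        m = train_svc(X, t, C=C, **TIGHT)
        assert np.all(m.alphas >= -1e-12) and np.all(m.alphas <= C + 1e-12)
        # duality gap: primal soft-margin objective minus dual objective
        scores = decision_value(m, X)
        primal = 0.5 * m.w @ m.w + C * np.clip(1 - t * scores, 0, None).sum()
        assert 0 <= primal - dual_objective(m) < 1e-6

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_svc(np.zeros((4, 2)), np.ones(4), C=1.0)

    def test_invalid_hyperparameters_rejected(self):
        X = np.array([[-1.0], [1.0]])
        t = np.array([-1.0, 1.0])
        with pytest.raises(ValueError):
            train_svc(X, t, C=0.0)
        with pytest.raises(ValueError):
            train_svc(X, t, C=1.0, kernel_scale=0.0)

    def test_dual_primal_consistency(self):
        """w equals the dual expansion sum alpha_n t_n x_n / s."""
        rng = np.random.default_rng(3)
        X, t = random_svc_instance(rng)
        m = train_svc(X, t, C=2.0, kernel_scale=2.0, **TIGHT)
        np.testing.assert_allclose(m.w, (m.alphas * t) @ (X / 2.0), atol=1e-8)


class TestSVR:
    def test_realizable_linear_regression(self):
        # spanning [-2, 2] pins the flattest in-tube slope at 2 - eps/2 = 1.95
        x = np.linspace(-2, 2, 15)
        X = x[:, None]
        t = 2.0 * x
        m = train_svr(X, t, C=1e4, epsilon=0.1, **TIGHT)
        assert m.w[0] == pytest.approx(2.0, abs=0.05 + 1e-9)
        resid = np.abs(decision_value(m, X) - t)
        assert np.all(resid <= 0.1 + 1e-6)

    @pytest.mark.parametrize("C", [0.5, 10.0])
    def test_matches_qp_oracle(self, C):
        rng = np.random.default_rng(int(C * 10))
        for _ in range(5):
            n = int(rng.integers(5, 21))
            X = rng.normal(size=(n, 3))
            t = X @ rng.normal(size=3) + rng.normal(0, 0.3, size=n)
            eps = 0.2
            m = train_svr(X, t, C=C, epsilon=eps, **TIGHT)
            _, w_qp, obj_qp = qp_svr(X, t, C, eps)
            assert dual_objective(m) == pytest.approx(obj_qp, abs=1e-6)
            np.testing.assert_allclose(m.w, w_qp, atol=1e-4)
            assert max_kkt_violation(m) < 1e-7

    def test_points_inside_tube_have_zero_dual(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(12, 2))
        t = X[:, 0] + rng.normal(0, 0.05, size=12)
        m = train_svr(X, t, C=10.0, epsilon=0.3, **TIGHT)
        resid = np.abs(decision_value(m, X) - t)
        strict_inside = resid < 0.3 - 1e-6
        assert np.all(np.abs(m.alphas[strict_inside]) < 1e-8)

    def test_degenerate_tube_zero_weights(self):
        t = np.array([0.1, -0.1, 0.05, 0.0])
        X = np.eye(4)
        m = train_svr(X, t, C=5.0, epsilon=1.0, **TIGHT)
        np.testing.assert_allclose(m.w, 0, atol=1e-10)
        assert len(m.support_) == 0
        assert np.all(np.abs(t - m.b) <= 1.0 + 1e-9)


class TestDecision:
    def test_linear_score_and_label(self):
        from pdpattern.svm import SVMSolution

        m = SVMSolution(mode="classify", w=np.array([1.0, 0.0]), b=0.0,
                        alphas=np.zeros(2), C=1.0, kernel_scale=1.0)
        assert decision_value(m, np.array([3.0, 5.0])) == pytest.approx(3.0)
        assert classify(m, np.array([3.0, 5.0])) == 1

    def test_boundary_tie_maps_to_positive(self):
        from pdpattern.svm import SVMSolution

        m = SVMSolution(mode="classify", w=np.array([1.0]), b=0.0,
                        alphas=np.zeros(1), C=1.0, kernel_scale=1.0)
        assert classify(m, np.array([0.0])) == 1

    def test_negation_flips_scores(self):
        from pdpattern.svm import SVMSolution

        rng = np.random.default_rng(2)
        w = rng.normal(size=3)
        m = SVMSolution("classify", w, 0.7, np.zeros(3), 1.0, 1.0)
        mneg = SVMSolution("classify", -w, -0.7, np.zeros(3), 1.0, 1.0)
        x = rng.normal(size=(5, 3))
        np.testing.assert_allclose(decision_value(mneg, x), -decision_value(m, x))

    def test_dimension_mismatch_rejected(self):
        from pdpattern.svm import SVMSolution

        m = SVMSolution("classify", np.ones(2), 0.0, np.zeros(2), 1.0, 1.0)
        with pytest.raises(ValueError):
            decision_value(m, np.ones(3))


class TestInvariances:
    def test_kernel_scale_equivalent_to_feature_rescaling(self):
        rng = np.random.default_rng(9)
        X, t = random_svc_instance(rng)
        m1 = train_svc(X, t, C=1.0, kernel_scale=2.0, **TIGHT)
        m2 = train_svc(X / 2.0, t, C=1.0, kernel_scale=1.0, **TIGHT)
        np.testing.assert_allclose(
            decision_value(m1, X), decision_value(m2, X / 2.0), atol=1e-6
        )

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(10)
        X, t = random_svc_instance(rng)
        perm = rng.permutation(len(t))
        m1 = train_svc(X, t, C=1.0, **TIGHT)
        m2 = train_svc(X[perm], t[perm], C=1.0, **TIGHT)
        np.testing.assert_allclose(m1.w, m2.w, atol=1e-8)
        assert m1.b == pytest.approx(m2.b, abs=1e-8)


class TestGridSearch:
    def well_separated(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(-3, 0.3, (10, 2)), rng.normal(3, 0.3, (10, 2))])
        t = np.concatenate([-np.ones(10), np.ones(10)])
        return X, t

    def test_tie_break_selects_smallest_C_then_scale(self):
        X, t = self.well_separated()
        res = grid_search_nested_cv(
            X, t, C_grid=[0.1, 1.0, 10.0], scale_grid=[0.5, 1.0], k=5, seed=0
        )
        zero_loss = res.table[res.table.cv_loss == res.cv_loss]
        assert res.C == zero_loss.C.min()
        assert res.kernel_scale == zero_loss[zero_loss.C == res.C].kernel_scale.min()

    def test_deterministic_for_fixed_seed(self):
        X, t = self.well_separated()
        r1 = grid_search_nested_cv(X, t, [0.1, 1.0], [1.0], k=4, seed=3)
        r2 = grid_search_nested_cv(X, t, [0.1, 1.0], [1.0], k=4, seed=3)
        assert (r1.C, r1.kernel_scale, r1.cv_loss) == (r2.C, r2.kernel_scale, r2.cv_loss)
        np.testing.assert_array_equal(r1.table.cv_loss, r2.table.cv_loss)

    def test_single_grid_point_returned(self):
        X, t = self.well_separated()
        res = grid_search_nested_cv(X, t, [2.0], [1.5], k=4, seed=0)
        assert (res.C, res.kernel_scale) == (2.0, 1.5)
        assert 0.0 <= res.cv_loss <= 1.0

    def test_fold_count_exceeding_class_size_rejected(self):
        X = np.vstack([np.ones((3, 2)), -np.ones((8, 2))])
        t = np.concatenate([np.ones(3), -np.ones(8)])
        with pytest.raises(ValueError, match="class size"):
            grid_search_nested_cv(X, t, [1.0], [1.0], k=5, seed=0)

    def test_regression_mode_selects_low_error_settings(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 2))
        t = X @ np.array([1.0, -2.0])
        res = grid_search_nested_cv(
            X, t, C_grid=[1e-3, 10.0], scale_grid=[1.0], k=5, seed=0, mode="regress"
        )
        assert res.C == 10.0  # strong regularization cannot fit the slope
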
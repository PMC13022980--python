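"""cKAN head: spline bank, stage flow, regularizer, gradients, training."""

import numpy as np
import pytest

from retikan import ckan as C
from retikan.ckan import (CkanConfig, SplineBank, bspline_basis, ckan_forward,
                          ckan_forward_stages, dense_head_param_count,
                          head_param_count, init_head_params, spline_apply,
                          spline_regularizer, train_head)


def cox_de_boor(x: float, i: int, k: int, t: np.ndarray) -> float:
    """Textbook recursive Cox-de Boor evaluation of one basis function."""
    if k == 0:
        # half-open intervals, closed at the right end of the domain
        if t[i] <= x < t[i + 1]:
            return 1.0
        if x == t[-1] and t[i] < t[i + 1] <= t[-1] and t[i + 1] == t[-1]:
            return 1.0
        return 0.0
    left = 0.0
    if t[i + k] > t[i]:
        left = (x - t[i]) / (t[i + k] - t[i]) * cox_de_boor(x, i, k - 1, t)
    right = 0.0
    if t[i + k + 1] > t[i + 1]:
        right = ((t[i + k + 1] - x) / (t[i + k + 1] - t[i + 1])
                 * cox_de_boor(x, i + 1, k - 1, t))
    return left + right


class TestSplineBank:
    def test_partition_of_unity(self):
        bank = SplineBank(1)
        x = np.random.default_rng(0).uniform(-2, 2, 200)
        np.testing.assert_allclose(bspline_basis(x, bank).sum(-1), 1.0,
                                   atol=1e-10)

    def test_clamped_left_boundary(self):
        bank = SplineBank(1)
        basis = bspline_basis(-2.0, bank)
        assert basis[0] == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(basis[1:], 0.0, atol=1e-12)

    def test_matches_recursive_cox_de_boor(self):
        bank = SplineBank(1)
        x = np.random.default_rng(1).uniform(-2, 2, 50)
        mine = bspline_basis(x, bank)
        for j, xv in enumerate(x):
            ref = [cox_de_boor(float(xv), i, 3, bank.knots)
                   for i in range(bank.n_basis)]
            np.testing.assert_allclose(mine[j], ref, atol=1e-10)

    def test_matches_scipy_design_matrix(self):
        from scipy.interpolate import BSpline
        bank = SplineBank(1)
        x = np.random.default_rng(2).uniform(-2, 2, 64)
        ref = BSpline.design_matrix(x, bank.knots, 3).toarray()
        np.testing.assert_allclose(bspline_basis(x, bank), ref, atol=1e-12)

    def test_identity_coefficients_reproduce_identity(self):
        bank = SplineBank(4)
        x = np.random.default_rng(3).uniform(-2, 2, (30, 4))
        np.testing.assert_allclose(spline_apply(x, bank), x, atol=1e-10)

    def test_out_of_span_clamps_to_boundary_value(self):
        bank = SplineBank(2)
        inside = spline_apply(np.array([[2.0, -2.0]]), bank)
        outside = spline_apply(np.array([[5.0, -7.0]]), bank)
        np.testing.assert_allclose(outside, inside, atol=1e-12)

    def test_bad_coefficient_shape_rejected(self):
        with pytest.raises(ValueError, match="coefficients"):
            SplineBank(3, coefficients=np.zeros((3, 4)))


class TestForward:
    def test_stage_shapes_follow_tensor_flow(self):
        cfg = CkanConfig()
        params = init_head_params(cfg, 0)
        z = np.random.default_rng(0).normal(size=(1, 14, 14, 256))
        st = ckan_forward_stages(z, cfg, params)
        assert st["condensed"].shape == (1, 14, 14, 128)
        assert st["spline"].shape == (1, 14, 14, 128)
        assert st["mixed"].shape == (1, 14, 14, 256)
        assert st["pooled"].shape == (1, 256)
        assert st["probs"].shape == (1, 5)
        assert st["probs"].sum() == pytest.approx(1.0, abs=1e-6)

    def test_identity_spline_reduces_stage2_to_its_input(self):
        cfg = CkanConfig(dropout=0.0)
        params = init_head_params(cfg, 0, dtype=np.float64)
        z = np.random.default_rng(1).normal(size=(2, 14, 14, 256))
        st = ckan_forward_stages(z, cfg, params)
        bank = SplineBank(cfg.condensed_channels, coefficients=params["spline_coef"])
        np.testing.assert_allclose(st["spline"],
                                   bank.clamp(st["pre_spline"]), atol=1e-5)

    def test_channel_mismatch_names_stage(self):
        cfg = CkanConfig()
        params = init_head_params(cfg, 0)
        with pytest.raises(ValueError, match="stage 1"):
            ckan_forward(np.zeros((1, 14, 14, 100)), cfg, params)

    def test_probability_rows_sum_to_one(self):
        cfg = CkanConfig()
        params = init_head_params(cfg, 3)
        z = np.random.default_rng(3).normal(size=(7, 14, 14, 256))
        probs = ckan_forward(z, cfg, params)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs >= 0).all()


class TestRegularizer:
    def test_zero_coefficients_give_zero(self):
        assert spline_regularizer(np.zeros((4, 10)), 1.0, 1.0) == 0.0

    def test_single_nonzero_coefficient_has_zero_entropy(self):
        c = np.zeros((1, 10))
        c[0, 3] = 2.0
        assert spline_regularizer(c, 0.0, 1.0) == pytest.approx(0.0)

    def test_two_equal_coefficients_give_log2_entropy(self):
        c = np.zeros((1, 10))
        c[0, 1], c[0, 7] = 1.5, -1.5
        assert spline_regularizer(c, 0.0, 1.0) == pytest.approx(np.log(2))

    def test_l1_term(self):
        c = np.full((2, 5), -0.4)
        assert spline_regularizer(c, 2.0, 0.0) == pytest.approx(0.8)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            spline_regularizer(np.ones((1, 3)), -1.0, 0.0)

    def test_objective_scales_monotonically_with_lambda(self):
        rng = np.random.default_rng(5)
        z = rng.normal(size=(3, 4, 4, 6))
        y = np.array([0, 1, 2])
        losses = []
        for lam in (0.0, 1e-3, 1e-1):
            cfg = CkanConfig(in_channels=6, condensed_channels=5,
                             out_channels=6, n_classes=3, dropout=0.0,
                             lam=lam)
            params = init_head_params(cfg, 0, dtype=np.float64)
            loss, ce, _, _ = C._forward_backward(z, y, cfg, params, None)
            losses.append(loss - ce)
        assert losses[0] == 0.0
        assert losses[0] <= losses[1] <= losses[2]


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self):
        """Full-parameter check on a 5-channel micro instance (float64)."""
        cfg = CkanConfig(in_channels=6, condensed_channels=5, out_channels=6,
                         n_classes=3, dropout=0.0, lam=1e-2)
        params = init_head_params(cfg, 0, dtype=np.float64)
        rng = np.random.default_rng(3)
        params["spline_coef"] = params["spline_coef"] + rng.normal(
            0, 0.3, params["spline_coef"].shape)
        z = rng.normal(size=(3, 4, 4, 6))
        y = np.array([0, 1, 2])
        _, _, grads, _ = C._forward_backward(z, y, cfg, params, None)
        eps = 1e-6
        for name in ("spline_coef", "w1", "b1", "dw", "dw_b", "bn_gamma",
                     "bn_beta", "w3", "b3", "w5", "b5"):
            g = grads[name]
            flat_idx = np.unravel_index(
                np.argsort(np.abs(g), axis=None)[-4:], g.shape)
            for idx in zip(*flat_idx):
                p2 = {k: v.copy() for k, v in params.items()}
                p2[name][idx] += eps
                lp, *_ = C._forward_backward(z, y, cfg, p2, None)
                p2[name][idx] -= 2 * eps
                lm, *_ = C._forward_backward(z, y, cfg, p2, None)
                num = (lp - lm) / (2 * eps)
                rel = abs(g[idx] - num) / max(1e-8, abs(num) + abs(g[idx]))
                assert rel < 1e-4, (name, idx, g[idx], num)


class TestTraining:
    @staticmethod
    def _separable_features(n=500, grid=4, channels=16, seed=0):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 5, n)
        centers = rng.normal(0, 2.0, (5, channels))
        z = centers[y][:, None, None, :] + rng.normal(
            0, 0.4, (n, grid, grid, channels))
        return z.astype(np.float32), y

    def test_learns_linearly_separable_classes(self):
        z, y = self._separable_features()
        cfg = CkanConfig(in_channels=16, condensed_channels=8,
                         out_channels=16, dropout=0.0)
        params, _ = train_head(z, y, cfg, epochs=30, lr=3e-3, seed=0)
        acc = (ckan_forward(z, cfg, params).argmax(1) == y).mean()
        assert acc >= 0.95
        # independent oracle: multinomial logistic regression on the same data
        from sklearn.linear_model import LogisticRegression
        flat = z.reshape(len(z), -1)
        oracle = LogisticRegression(max_iter=500).fit(flat, y)
        assert oracle.score(flat, y) >= 0.95

    def test_same_seed_identical_loss_history(self):
        z, y = self._separable_features(n=60)
        cfg = CkanConfig(in_channels=16, condensed_channels=8,
                         out_channels=16)
        _, h1 = train_head(z, y, cfg, epochs=3, seed=5)
        _, h2 = train_head(z, y, cfg, epochs=3, seed=5)
        assert h1["train_loss"] == h2["train_loss"]

    def test_lambda_zero_objective_equals_prediction_loss(self):
        z, y = self._separable_features(n=40)
        cfg = CkanConfig(in_channels=16, condensed_channels=8,
                         out_channels=16, lam=0.0, dropout=0.0)
        params = init_head_params(cfg, 0, dtype=np.float64)
        loss, ce, _, _ = C._forward_backward(
            z.astype(np.float64), y, cfg, params, None)
        assert loss == ce

    def test_empty_or_degenerate_training_sets_rejected(self):
        cfg = CkanConfig(in_channels=16, condensed_channels=8,
                         out_channels=16)
        with pytest.raises(ValueError, match="empty"):
            train_head(np.zeros((0, 4, 4, 16)), np.zeros(0, int), cfg)
        with pytest.raises(ValueError, match="2 classes"):
            train_head(np.zeros((5, 4, 4, 16)), np.zeros(5, int), cfg)

    def test_early_stopping_restores_best_epoch(self):
        z, y = self._separable_features(n=80)
        cfg = CkanConfig(in_channels=16, condensed_channels=8,
                         out_channels=16, dropout=0.0)
        _, hist = train_head(z[:60], y[:60], cfg, val_features=z[60:],
                             val_labels=y[60:], epochs=25, patience=3,
                             lr=3e-3, seed=1)
        assert len(hist["val_loss"]) <= 25


def test_head_is_smaller_than_dense_head():
    cfg = CkanConfig()
    assert head_param_count(cfg) < dense_head_param_count(cfg, grid=14)
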
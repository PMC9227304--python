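"""Capsule-network math: squashing, routing, shapes, loss, gradients."""

import numpy as np
import pytest

import ramancaps.capsnet as cn
from ramancaps.capsnet import (
    AdamState,
    CapsNetConfig,
    dynamic_routing,
    forward,
    init_params,
    load_checkpoint,
    margin_loss,
    predict_uhat,
    save_checkpoint,
    squash,
)

DEFAULT = CapsNetConfig()


def straight_line_routing(u_hat, iterations):
    """Independent loop-explicit oracle for agreement routing.

    Scalar loops only; mirrors the published update equations directly.
    """
    n_i, n_j, d = u_hat.shape
    b = np.zeros((n_i, n_j))
    for it in range(iterations):
        c = np.zeros_like(b)
        for i in range(n_i):
            exps = [np.exp(b[i, j]) for j in range(n_j)]
            for j in range(n_j):
                c[i, j] = exps[j] / sum(exps)
        s = np.zeros((n_j, d))
        for j in range(n_j):
            for i in range(n_i):
                s[j] += c[i, j] * u_hat[i, j]
        v = np.zeros_like(s)
        for j in range(n_j):
            norm = np.sqrt(np.sum(s[j] ** 2))
            if norm > 0:
                v[j] = (norm**2 / (1 + norm**2)) * (s[j] / norm)
        if it < iterations - 1:
            for i in range(n_i):
                for j in range(n_j):
                    b[i, j] += float(np.dot(v[j], u_hat[i, j]))
    return c, s, v


class TestSquash:
    def test_zero_maps_to_zero(self):
        np.testing.assert_array_equal(squash(np.zeros(8)), np.zeros(8))

    def test_unit_norm_halved(self):
        s = np.zeros(5)
        s[2] = 1.0
        assert abs(np.linalg.norm(squash(s)) - 0.5) < 1e-12

    def test_norm_three_gives_point_nine(self):
        s = np.array([3.0, 0.0, 0.0])
        v = squash(s)
        np.testing.assert_allclose(v, [0.9, 0.0, 0.0], atol=1e-12)

    def test_norm_bounded_and_monotone(self, rng):
        direction = rng.normal(size=6)
        direction /= np.linalg.norm(direction)
        norms = [np.linalg.norm(squash(r * direction)) for r in np.linspace(0.01, 50, 200)]
        assert all(0 <= n < 1 for n in norms)
        assert all(a < b for a, b in zip(norms, norms[1:]))

    def test_direction_preserved(self, rng):
        s = rng.normal(size=4)
        v = squash(s)
        cos = np.dot(s, v) / (np.linalg.norm(s) * np.linalg.norm(v))
        assert abs(cos - 1) < 1e-12


class TestPredictUhat:
    def test_identity_transform(self, rng):
        u = rng.normal(size=(5, 4))
        W = np.broadcast_to(np.eye(4), (5, 3, 4, 4)).copy()
        u_hat = predict_uhat(u, W)
        for j in range(3):
            np.testing.assert_allclose(u_hat[:, j, :], u)

    def test_zero_transform(self, rng):
        u = rng.normal(size=(5, 4))
        np.testing.assert_array_equal(predict_uhat(u, np.zeros((5, 3, 2, 4))), 0)

    def test_matches_hand_computed_products(self, rng):
        u = rng.normal(size=(2, 2))
        W = rng.normal(size=(2, 1, 2, 2))
        u_hat = predict_uhat(u, W)
        for i in range(2):
            np.testing.assert_allclose(u_hat[i, 0], W[i, 0] @ u[i])

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="shape"):
            predict_uhat(rng.normal(size=(2, 3)), rng.normal(size=(2, 1, 2, 2)))


class TestRouting:
    def test_initial_couplings_uniform_over_three_classes(self, rng):
        u_hat = rng.normal(size=(10, 3, 4))
        state = dynamic_routing(u_hat, iterations=1)
        np.testing.assert_allclose(state.c, 1.0 / 3.0, atol=1e-12)

    def test_zero_predictions_give_zero_output_and_uniform_c(self):
        state = dynamic_routing(np.zeros((6, 3, 4)), iterations=4)
        np.testing.assert_array_equal(state.v, 0)
        np.testing.assert_allclose(state.c, 1.0 / 3.0, atol=1e-12)

    @pytest.mark.parametrize("iterations", [1, 2, 3, 5])
    def test_matches_straight_line_oracle(self, rng, iterations):
        u_hat = rng.normal(size=(3, 3, 4))
        state = dynamic_routing(u_hat, iterations)
        c, s, v = straight_line_routing(u_hat, iterations)
        np.testing.assert_allclose(state.c, c, atol=1e-10)
        np.testing.assert_allclose(state.s, s, atol=1e-10)
        np.testing.assert_allclose(state.v, v, atol=1e-10)

    def test_two_capsule_two_class_hand_stepped(self, rng):
        u_hat = rng.normal(size=(2, 2, 2))
        state = dynamic_routing(u_hat, iterations=2)
        c, s, v = straight_line_routing(u_hat, 2)
        np.testing.assert_allclose(state.v, v, atol=1e-10)
        np.testing.assert_allclose(state.c, c, atol=1e-10)

    def test_couplings_normalized_every_iteration(self, rng):
        for iterations in (1, 2, 3, 4):
            state = dynamic_routing(rng.normal(size=(7, 3, 5)), iterations)
            np.testing.assert_allclose(state.c.sum(axis=-1), 1.0, atol=1e-9)

    def test_one_iteration_equals_uniform_average(self, rng):
        # with 3 primary capsules and c = 1/3, the class input is exactly
        # the unweighted mean of the predictions
        u_hat = rng.normal(size=(3, 3, 4))
        state = dynamic_routing(u_hat, iterations=1)
        np.testing.assert_allclose(state.v, squash(u_hat.mean(axis=0)), atol=1e-12)

    def test_non_finite_input_raises(self):
        bad = np.zeros((2, 3, 4))
        bad[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            dynamic_routing(bad)


class TestForward:
    def test_geometry_chain(self, tiny_net_cfg):
        assert DEFAULT.conv1_grid == 20
        assert DEFAULT.primary_grid == 6
        assert DEFAULT.primary_caps_types == 32
        assert DEFAULT.n_primary == 1152
        assert tiny_net_cfg.conv1_grid == 20 and tiny_net_cfg.primary_grid == 6

    def test_lengths_in_unit_interval(self, tiny_net_cfg, rng):
        params = init_params(tiny_net_cfg, seed=0)
        lengths, state = forward(rng.normal(size=(28, 28)), params, tiny_net_cfg)
        assert lengths.shape == (3,)
        assert np.all(lengths >= 0) and np.all(lengths < 1)
        assert state.u_hat.shape[0] == tiny_net_cfg.n_primary

    def test_forward_is_deterministic(self, tiny_net_cfg, rng):
        params = init_params(tiny_net_cfg, seed=0)
        img = rng.normal(size=(28, 28))
        l1, _ = forward(img, params, tiny_net_cfg)
        l2, _ = forward(img, params, tiny_net_cfg)
        np.testing.assert_array_equal(l1, l2)

    def test_wrong_image_shape_raises(self, tiny_net_cfg, rng):
        params = init_params(tiny_net_cfg, seed=0)
        with pytest.raises(ValueError):
            forward(rng.normal(size=(27, 27)), params, tiny_net_cfg)


class TestMarginLoss:
    def test_zero_iff_margins_satisfied(self):
        assert margin_loss(np.array([0.95, 0.05, 0.02]), 0) == 0.0
        assert margin_loss(np.array([0.95, 0.05, 0.11]), 0) > 0.0
        assert margin_loss(np.array([0.89, 0.05, 0.02]), 0) > 0.0

    def test_all_zero_lengths(self):
        assert abs(margin_loss(np.zeros(3), 1) - 0.81) < 1e-12

    def test_all_unit_lengths(self):
        assert abs(margin_loss(np.ones(3), 2) - 0.5 * 2 * 0.81) < 1e-12

    def test_invalid_label_raises(self):
        with pytest.raises(ValueError, match="label"):
            margin_loss(np.zeros(3), 5)

    def test_non_negative_on_random_lengths(self, rng):
        for _ in range(50):
            assert margin_loss(rng.uniform(size=3), int(rng.integers(3))) >= 0


class TestInitParams:
    def test_seed_reproducibility(self, tiny_net_cfg):
        a, b = init_params(tiny_net_cfg, 42), init_params(tiny_net_cfg, 42)
        for k, arr in a.as_dict().items():
            np.testing.assert_array_equal(arr, b.as_dict()[k])

    def test_default_shapes(self):
        p = init_params(DEFAULT, 0)
        assert p.W.shape == (1152, 3, 16, 8)
        assert p.conv1_w.shape == (256, 1, 9, 9)
        p.validate(DEFAULT)

    def test_validate_rejects_wrong_shape(self, tiny_net_cfg):
        p = init_params(tiny_net_cfg, 0)
        p.W = p.W[:, :2]
        with pytest.raises(ValueError, match="shape"):
            p.validate(tiny_net_cfg)


class TestGradients:
    @pytest.mark.parametrize("iterations", [1, 3])
    def test_backprop_matches_finite_differences(self, iterations, rng):
        cfg = CapsNetConfig(
            conv1_channels=3, primary_channels=8, class_caps_dim=4,
            w_init_std=0.5, routing_iterations=iterations,
        )
        params = init_params(cfg, 1)
        x = rng.normal(size=(2, 1, 28, 28)) * 0.3
        labels = np.array([0, 2])
        _, grads, _ = cn.loss_and_grads(x, labels, params, cfg)
        eps = 1e-6
        for key in ("conv1_w", "conv1_b", "conv2_w", "conv2_b", "W"):
            arr = params.as_dict()[key]
            flat = arr.ravel()
            for i in rng.choice(arr.size, size=min(4, arr.size), replace=False):
                old = flat[i]
                flat[i] = old + eps
                lp, _, _ = cn.loss_and_grads(x, labels, params, cfg)
                flat[i] = old - eps
                lm, _, _ = cn.loss_and_grads(x, labels, params, cfg)
                flat[i] = old
                num = (lp - lm) / (2 * eps)
                ana = grads[key].ravel()[i]
                assert abs(num - ana) <= 1e-4 * max(1.0, abs(num) + abs(ana)), (
                    f"{key}[{i}]: numeric {num} vs analytic {ana}"
                )

    def test_adam_reduces_loss_on_fixed_batch(self, tiny_net_cfg, rng):
        params = init_params(tiny_net_cfg, 3)
        opt = AdamState(params, lr=5e-3)
        x = rng.normal(size=(6, 1, 28, 28)) * 0.2
        labels = np.array([0, 1, 2, 0, 1, 2])
        first, _, _ = cn.loss_and_grads(x, labels, params, tiny_net_cfg)
        for _ in range(30):
            _, grads, _ = cn.loss_and_grads(x, labels, params, tiny_net_cfg)
            opt.step(params, grads)
        last, _, _ = cn.loss_and_grads(x, labels, params, tiny_net_cfg)
        assert last < first


class TestCheckpoint:
    def test_round_trip(self, tiny_net_cfg, tmp_path):
        params = init_params(tiny_net_cfg, 9)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, params, tiny_net_cfg, seed=9)
        loaded, cfg2, seed = load_checkpoint(path)
        assert cfg2 == tiny_net_cfg and seed == 9
        for k, arr in params.as_dict().items():
            np.testing.assert_array_equal(arr, loaded.as_dict()[k])

    def test_mismatched_shapes_rejected(self, tiny_net_cfg, tmp_path):
        params = init_params(tiny_net_cfg, 9)
        path = tmp_path / "ckpt.npz"
        other = CapsNetConfig(conv1_channels=4, primary_channels=8, class_caps_dim=4)
        save_checkpoint(path, params, other, seed=9)
        with pytest.raises(ValueError, match="shape"):
            load_checkpoint(path)
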
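"""Tests for the hybrid SLS + neural-residual model and its training loop."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from adhesiokin import SLSParams, TrainConfig, sls_mean, train_pinn
from adhesiokin.mlp import MLP, MLPSpec
from adhesiokin.pinn import (PINNState, correction_curve, data_loss,
                             hybrid_predict, init_state, nn_correction,
                             nn_correction_and_derivative, normalize_time,
                             physics_loss, total_loss)

BACKBONE = SLSParams(F0=50.0, Fmax=350.0, tau=3.0)


def _random_state(seed: int, t_max: float = 10.0) -> PINNState:
    """State with a non-trivial (randomized) output layer."""
    rng = np.random.default_rng(seed)
    net = MLP.init(MLPSpec(), rng)
    net.Ws[-1] = rng.normal(0.0, 0.5, net.Ws[-1].shape)
    net.bs[-1] = rng.normal(0.0, 0.5, net.bs[-1].shape)
    return PINNState(net=net, s_data=0.0, s_phys=0.0, backbone=BACKBONE,
                     var_data=100.0, t_max=t_max)


def _zero_state(t_max: float = 10.0) -> PINNState:
    net = MLP.init(MLPSpec(), np.random.default_rng(0))
    return PINNState(net=net, s_data=0.0, s_phys=0.0, backbone=BACKBONE,
                     var_data=100.0, t_max=t_max)


class TestNormalizeTime:
    @pytest.mark.parametrize("t, t_max, expected",
                             [(0.0, 10.0, 0.0), (10.0, 10.0, 1.0),
                              (4.0, 10.0, 0.4)])
    def test_values(self, t, t_max, expected):
        assert normalize_time(t, t_max) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            normalize_time(1.0, 0.0)
        with pytest.raises(ValueError):
            normalize_time(11.0, 10.0)


class TestCorrectionNetwork:
    def test_fresh_network_outputs_zero(self):
        """Zero-initialized output layer: the correction vanishes
        everywhere, so the hybrid model starts exactly at the backbone."""
        state = _zero_state()
        grid = np.linspace(0.0, 10.0, 1000)
        np.testing.assert_array_equal(correction_curve(state, grid), 0.0)
        np.testing.assert_allclose(hybrid_predict(state, grid),
                                   sls_mean(BACKBONE, grid), atol=1e-9)
        assert physics_loss(state, grid) == 0.0

    def test_deterministic_forward(self):
        state = _random_state(3)
        t = np.linspace(0.0, 10.0, 17)
        np.testing.assert_array_equal(nn_correction(state, t),
                                      nn_correction(state, t))

    def test_hybrid_is_backbone_plus_correction(self):
        state = _random_state(4)
        t = np.linspace(0.0, 10.0, 50)
        np.testing.assert_allclose(
            hybrid_predict(state, t) - sls_mean(BACKBONE, t),
            nn_correction(state, t), atol=1e-12)

    def test_scalar_grid_consistency(self):
        state = _random_state(5)
        assert correction_curve(state, [4.0])[0] == nn_correction(state, 4.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_time_derivative_matches_finite_differences(self, seed):
        """The forward-tangent derivative agrees with central differences
        (h = 1e-4) to 1e-4 relative error on randomized networks."""
        state = _random_state(seed)
        t = np.random.default_rng(seed).uniform(0.1, 9.9, 20)
        _, deriv = nn_correction_and_derivative(state, t)
        h = 1e-4
        fd = (nn_correction(state, t + h) - nn_correction(state, t - h)) / (2 * h)
        np.testing.assert_allclose(deriv, fd, rtol=1e-4, atol=1e-8)

    def test_parameter_gradients_match_finite_differences(self):
        """Backprop through the value+tangent graph agrees with numerical
        differentiation of a loss involving both the output and dF/dt."""
        state = _random_state(1)
        net = state.net
        x = np.linspace(0.0, 1.0, 15)[:, None]
        xt = np.full_like(x, 0.1)

        yv, ytan, cache = net.forward(x, xt)
        gW, gb = net.backward(cache, 2.0 * yv, 2.0 * ytan)
        grad = net.flat_grad(gW, gb)

        flat = net.get_flat()

        def loss(f):
            net.set_flat(f)
            a, b, _ = net.forward(x, xt)
            return float(np.sum(a**2) + np.sum(b**2))

        rng = np.random.default_rng(0)
        for i in rng.choice(flat.size, 25, replace=False):
            fp = flat.copy(); fp[i] += 1e-6
            fm = flat.copy(); fm[i] -= 1e-6
            numeric = (loss(fp) - loss(fm)) / 2e-6
            assert numeric == pytest.approx(grad[i], rel=1e-4, abs=1e-8)


class _LinearCorrectionNet:
    """Stub network computing exactly F_NN(t) = slope * t (physical time)."""

    def __init__(self, slope: float, t_max: float):
        self.slope = slope
        self.t_max = t_max

    def forward(self, x, x_tan=None):
        y = self.slope * self.t_max * np.asarray(x)
        y_tan = None if x_tan is None else self.slope * self.t_max * np.asarray(x_tan)
        return y, y_tan, None


class _ConstantCorrectionNet:
    """Stub network returning a constant correction (zero derivative)."""

    def __init__(self, value: float):
        self.value = value

    def forward(self, x, x_tan=None):
        y = np.full_like(np.asarray(x, dtype=float), self.value)
        y_tan = None if x_tan is None else np.zeros_like(y)
        return y, y_tan, None


class TestLossTerms:
    @pytest.mark.parametrize("residual, expected",
                             [(0.0, 0.0), (0.5, 0.125), (2.0, 1.5)])
    def test_smooth_l1_branches(self, residual, expected):
        assert data_loss([residual], [0.0], threshold=1.0) == pytest.approx(expected)

    def test_data_loss_input_validation(self):
        with pytest.raises(ValueError):
            data_loss([1.0, 2.0], [1.0])

    def test_physics_loss_constant_correction(self):
        """Constant 10 pN correction, zero derivative, var 100 -> exactly 1,
        independent of the number of collocation points."""
        state = PINNState(net=_ConstantCorrectionNet(10.0), s_data=0.0,
                          s_phys=0.0, backbone=BACKBONE, var_data=100.0,
                          t_max=10.0)
        for m in (3, 50):
            assert physics_loss(state, np.linspace(0, 10, m)) == pytest.approx(1.0)

    def test_physics_loss_linear_correction_hand_sum(self):
        """Correction 2t on collocation {0,1,2} with unit variance gives
        (1/3) * [(0+4)+(4+4)+(16+4)] = 32/3."""
        state = PINNState(net=_LinearCorrectionNet(2.0, 2.0), s_data=0.0,
                          s_phys=0.0, backbone=BACKBONE, var_data=1.0,
                          t_max=2.0)
        assert physics_loss(state, [0.0, 1.0, 2.0]) == pytest.approx(32.0 / 3.0)

    def test_physics_loss_empty_collocation_rejected(self):
        with pytest.raises(ValueError):
            physics_loss(_zero_state(), [])

    def test_physics_loss_nonnegative_random_states(self):
        for seed in range(5):
            assert physics_loss(_random_state(seed), np.linspace(0, 10, 20)) >= 0.0

    @pytest.mark.parametrize(
        "ld, lp, sd, sp, expected",
        [(2.0, 1.0, 0.0, 0.0, 3.0),
         (4.0, 0.0, 1.0, 0.0, 4.0 / np.e + 1.0)],
    )
    def test_adaptive_total_loss_values(self, ld, lp, sd, sp, expected):
        assert total_loss(ld, lp, sd, sp, adaptive=True) == pytest.approx(expected)

    def test_fixed_weighting_is_plain_sum(self):
        assert total_loss(2.5, 1.5, 3.0, -1.0, adaptive=False) == 4.0

    @pytest.mark.parametrize("L", [0.5, 2.0, 7.3])
    def test_adaptive_stationarity_at_sigma2_equals_loss(self, L):
        """For a fixed component loss L, e^{-s} L + s is minimized at
        s = log L, i.e. at sigma^2 = L (checked by 1-D minimization)."""
        res = minimize_scalar(lambda s: np.exp(-s) * L + s,
                              bounds=(-10.0, 10.0), method="bounded",
                              options={"xatol": 1e-10})
        assert res.x == pytest.approx(np.log(L), abs=1e-6)
        assert res.fun == pytest.approx(1.0 + np.log(L), abs=1e-8)


class TestTraining:
    def test_same_seed_bitwise_identical(self, mild_dataset):
        cfg = TrainConfig(epochs=120, seed=7)
        backbone = SLSParams(F0=15.0, Fmax=300.0, tau=3.7)
        _, h1 = train_pinn(mild_dataset, backbone, cfg)
        _, h2 = train_pinn(mild_dataset, backbone, cfg)
        assert np.array_equal(h1.total, h2.total)
        assert np.array_equal(h1.weight_data, h2.weight_data)

    def test_history_shapes_and_finiteness(self, mild_dataset):
        cfg = TrainConfig(epochs=80, seed=1)
        backbone = SLSParams(F0=15.0, Fmax=300.0, tau=3.7)
        state, hist = train_pinn(mild_dataset, backbone, cfg)
        for arr in (hist.total, hist.data, hist.physics,
                    hist.weight_data, hist.weight_phys):
            assert arr.shape == (80,)
            assert np.all(np.isfinite(arr))
        assert state.backbone is backbone  # frozen by default

    def test_zero_noise_training_not_worse_than_backbone(self, noiseless_dataset):
        """On data generated exactly by the backbone, training starts at the
        backbone (zero output layer) and can only maintain or reduce the
        data loss."""
        from adhesiokin import fit_sls

        backbone = fit_sls(noiseless_dataset).params
        baseline = data_loss(sls_mean(backbone, noiseless_dataset.times),
                             noiseless_dataset.forces)
        _, hist = train_pinn(noiseless_dataset, backbone,
                             TrainConfig(epochs=300, seed=2))
        assert hist.data[-1] <= baseline + 1e-12

    def test_training_reduces_total_loss(self, mild_dataset):
        """Median total loss over the last 10% of epochs is no worse than
        over the first 10%."""
        from adhesiokin import fit_sls

        backbone = fit_sls(mild_dataset).params
        _, hist = train_pinn(mild_dataset, backbone,
                             TrainConfig(epochs=600, seed=3))
        k = 60
        assert np.median(hist.total[-k:]) <= np.median(hist.total[:k])

    def test_state_json_round_trip(self, mild_dataset):
        from adhesiokin import fit_sls

        backbone = fit_sls(mild_dataset).params
        state, _ = train_pinn(mild_dataset, backbone,
                              TrainConfig(epochs=50, seed=4))
        restored = PINNState.from_json(state.to_json())
        t = np.linspace(0.0, 10.0, 20)
        np.testing.assert_array_equal(hybrid_predict(restored, t),
                                      hybrid_predict(state, t))

    def test_init_state_reduces_to_backbone(self, mild_dataset):
        state = init_state(mild_dataset, BACKBONE, seed=0)
        t = np.linspace(0.0, mild_dataset.t_max, 100)
        np.testing.assert_allclose(hybrid_predict(state, t),
                                   sls_mean(BACKBONE, t), atol=1e-9)
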
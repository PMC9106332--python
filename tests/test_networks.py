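"""The modulator contract and the three feedforward architectures."""

import numpy as np
import pytest

import modinvar.autodiff as ad
from modinvar import networks
from modinvar.exceptions import InvalidParameterError
from modinvar.networks import (
    DaleanNet,
    Modulator,
    PopulationNet,
    SimpleModulatedNet,
    effective_weights,
    forward_dalean,
    forward_population,
    forward_simple,
    gain_from_modulation,
    modulator_step,
    step_filtered_modulation,
    step_population_modulation,
    von_mises_kernel,
)


def make_modulator(rng, n_hidden=6, n_out=4, **kw):
    return Modulator(2, n_hidden, n_out, rng=rng, **kw)


class TestModulator:
    def test_zero_state_zero_input_zero_biases_returns_readout_bias(self, rng):
        mod = make_modulator(rng)
        mod.b.data[:] = 0.0
        state = mod.init_state(1)
        feedback, _ = mod.step(np.zeros((1, 2)), np.zeros((1, 2)), state)
        np.testing.assert_allclose(feedback.data[0], mod.ro_b.data, atol=1e-12)

    def test_default_hidden_units(self, rng):
        net = SimpleModulatedNet(rng=rng)
        assert net.modulator.n_hidden == 100

    def test_stepping_is_deterministic_from_saved_state(self, rng):
        mod = make_modulator(rng)
        state = mod.init_state(1)
        x = rng.standard_normal((1, 2))
        y = rng.standard_normal((1, 2))
        f1, s1 = mod.step(x, y, state)
        f2, s2 = mod.step(x, y, state)
        np.testing.assert_array_equal(f1.data, f2.data)
        np.testing.assert_array_equal(s1[0].data, s2[0].data)
        np.testing.assert_array_equal(s1[1].data, s2[1].data)

    def test_dimension_mismatch_raises(self, rng):
        mod = make_modulator(rng)
        with pytest.raises(InvalidParameterError):
            mod.step(np.zeros((1, 3)), np.zeros((1, 2)), mod.init_state(1))

    def test_input_masks_zero_the_omitted_slice(self, rng):
        x = rng.standard_normal((1, 2))
        y = rng.standard_normal((1, 2))
        params = make_modulator(rng).parameters()
        params = {k: v.data for k, v in params.items()}
        out = {}
        for mode in ("x_and_y", "x_only", "y_only"):
            mod = Modulator(2, 6, 4, input_mode=mode, params=params)
            out[mode], _ = modulator_step(mod, x, y)
        # x_only ignores y; y_only ignores x
        mod = Modulator(2, 6, 4, input_mode="x_only", params=params)
        alt, _ = modulator_step(mod, x, np.zeros((1, 2)))
        np.testing.assert_array_equal(out["x_only"], alt)
        mod = Modulator(2, 6, 4, input_mode="y_only", params=params)
        alt, _ = modulator_step(mod, np.zeros((1, 2)), y)
        np.testing.assert_array_equal(out["y_only"], alt)
        assert not np.allclose(out["x_and_y"], out["x_only"])

    def test_invalid_input_mode(self, rng):
        with pytest.raises(InvalidParameterError):
            make_modulator(rng, input_mode="both")


class TestSimpleModel:
    def test_all_ones_modulation_is_baseline_map(self, rng):
        net = SimpleModulatedNet(n_hidden=4, rng=rng)
        net.W0 = ad.Tensor(np.eye(2))
        net.reset_state(1)  # M starts at ones
        x = rng.standard_normal(2)
        np.testing.assert_allclose(forward_simple(net, x), x, atol=1e-12)

    def test_inverse_modulation_recovers_sources(self, rng):
        net = SimpleModulatedNet(n_hidden=4, rng=rng)
        net.W0 = ad.Tensor(np.ones((2, 2)))
        net.reset_state(1)
        A = np.array([[0.7, 0.3], [0.2, 0.8]])
        net.M = ad.Tensor(np.linalg.inv(A)[None])
        s = rng.standard_normal(2)
        np.testing.assert_allclose(forward_simple(net, A @ s), s, atol=1e-12)

    def test_matches_hand_rolled_matrix_product(self, rng):
        net = SimpleModulatedNet(n_hidden=4, rng=rng)
        net.reset_state(1)
        net.M = ad.Tensor(rng.standard_normal((1, 2, 2)))
        x = rng.standard_normal(2)
        expected = (net.M.data[0] * net.W0.data) @ x
        np.testing.assert_allclose(forward_simple(net, x), expected, atol=1e-14)

    def test_step_uses_instantaneous_drive_without_tau(self, rng):
        net = SimpleModulatedNet(n_hidden=4, tau=None, rng=rng)
        net.reset_state(1)
        y, info = net.step(np.ones((1, 2)))
        # M equals the reshaped feedback readout
        np.testing.assert_allclose(
            info["M"].data[0].ravel(), info["l"].data[0], atol=1e-14
        )


class TestFilteredModulation:
    def test_tau_equals_dt_jumps_to_drive(self):
        M = np.array([[0.0, 2.0]])
        drive = np.array([[1.0, -1.0]])
        np.testing.assert_allclose(step_filtered_modulation(M, drive, 1.0, 1.0), drive)

    def test_geometric_convergence_to_constant_drive(self):
        tau, k = 10.0, 25
        M = np.array(0.0)
        for _ in range(k):
            M = step_filtered_modulation(M, 3.0, tau)
        residual = 3.0 - M
        np.testing.assert_allclose(residual, (1 - 1 / tau) ** k * 3.0, rtol=1e-12)

    def test_default_timescale(self, rng):
        assert PopulationNet(n_hidden=4, rng=rng).tau == 100.0

    def test_invalid_tau(self):
        with pytest.raises(InvalidParameterError):
            step_filtered_modulation(np.zeros(2), np.ones(2), 0.0)


class TestVonMisesKernel:
    def test_peak_value_at_matched_location(self):
        K = von_mises_kernel(4, 4, 0.2, normalize=False)
        np.testing.assert_allclose(np.diag(K), np.exp(1 / 0.2))

    def test_infinite_width_is_uniform(self):
        K = von_mises_kernel(8, 3, np.inf, normalize=False)
        np.testing.assert_array_equal(K, np.ones((8, 3)))

    def test_circulant_structure_and_direct_evaluation(self):
        K = von_mises_kernel(4, 4, 0.2, normalize=False)
        locs = 2 * np.pi * np.arange(4) / 4
        expected = np.exp(np.cos(locs[:, None] - locs[None, :]) / 0.2)
        np.testing.assert_allclose(K, expected, rtol=1e-12)
        np.testing.assert_allclose(K.sum(axis=1), K.sum(axis=1)[0])
        for shift in range(1, 4):
            np.testing.assert_allclose(K, np.roll(np.roll(K, shift, 0), shift, 1))

    def test_rotation_invariance(self):
        # cos depends only on the location difference: joint rotation of
        # units and preferred locations leaves the kernel unchanged
        theta = 0.37
        z = 2 * np.pi * np.arange(6) / 6
        l = 2 * np.pi * np.arange(3) / 3
        K1 = np.exp(np.cos(z[:, None] - l[None, :]) / 0.5)
        K2 = np.exp(np.cos((z + theta)[:, None] - (l + theta)[None, :]) / 0.5)
        np.testing.assert_allclose(K1, K2, rtol=1e-12)

    def test_normalized_rows_sum_to_one(self):
        K = von_mises_kernel(10, 4, 0.2, normalize=True)
        np.testing.assert_allclose(K.sum(axis=1), 1.0, atol=1e-12)


class TestPopulationModulation:
    def test_zero_feedback_keeps_zero(self):
        K = von_mises_kernel(5, 2, 0.2)
        m = step_population_modulation(np.zeros(5), np.zeros(2), K, 10.0)
        np.testing.assert_array_equal(m, np.zeros(5))

    def test_fixed_point_is_kernel_times_feedback(self):
        K = von_mises_kernel(5, 2, 0.2)
        l = np.array([1.0, -0.5])
        m = K @ l
        np.testing.assert_allclose(step_population_modulation(m, l, K, 7.0), m)

    def test_hand_euler_step(self):
        # tau=2, dt=1, m=1, Kl=3 -> m' = 1 + (1/2)(3 - 1) = 2
        m = step_population_modulation(np.array([1.0]), np.array([3.0]), np.eye(1), 2.0)
        np.testing.assert_allclose(m, [2.0])


class TestPopulationNet:
    def test_unit_modulation_passes_input_weights(self, rng):
        net = PopulationNet(n_hidden=4, n_z=6, rng=rng)
        net.reset_state(1)
        net.m = ad.Tensor(np.ones((1, 6)))
        x = rng.standard_normal(2)
        z, y = forward_population(net, x)
        np.testing.assert_allclose(z, net.Wx.data @ x, atol=1e-12)

    def test_defaults(self, rng):
        net = PopulationNet(n_hidden=4, rng=rng)
        assert net.n_z == 100 and net.n_fb == 4 and net.sigma_m_sq == 0.2

    def test_matches_two_line_oracle(self, rng):
        net = PopulationNet(n_hidden=4, n_z=6, rng=rng)
        net.reset_state(1)
        net.m = ad.Tensor(rng.standard_normal((1, 6)))
        x = rng.standard_normal(2)
        z, y = forward_population(net, x)
        z_expected = net.m.data[0] * (net.Wx.data @ x)
        np.testing.assert_allclose(z, z_expected, atol=1e-13)
        np.testing.assert_allclose(y, net.Wro.data @ z_expected, atol=1e-13)

    def test_class_step_consistent_with_pure_functions(self, rng):
        net = PopulationNet(n_hidden=4, n_z=6, tau=5.0, rng=rng)
        net.reset_state(1)
        x = rng.standard_normal((1, 2))
        with ad.no_grad():
            l, _ = net.modulator.step(x, np.zeros((1, 2)), net.modulator.init_state(1))
            m_expected = step_population_modulation(
                np.zeros(6), l.data[0], net.K.data, 5.0
            )
            y, info = net.step(x)
        np.testing.assert_allclose(info["m"].data[0], m_expected, atol=1e-12)


class TestGain:
    def test_values(self):
        assert gain_from_modulation(0.0) == pytest.approx(0.5)
        assert gain_from_modulation(np.log(3.0)) == pytest.approx(0.25)

    def test_monotone_decreasing_and_bounded(self):
        m = np.linspace(-20, 20, 201)
        p = gain_from_modulation(m)
        assert (np.diff(p) < 0).all()
        assert (p > 0).all() and (p < 1).all()


class TestDaleanNet:
    def test_nonpositive_drive_silences_everything(self, rng):
        net = DaleanNet(n_hidden=4, n_l=5, n_h=6, n_i=3, rng=rng)
        net.reset_state(1)
        net.WLx = ad.Tensor(np.abs(net.WLx.data), requires_grad=True)
        zL, zI, zH, y = forward_dalean(net, np.array([-1.0, -1.0]))
        assert (zL == 0).all() and (zH == 0).all()
        np.testing.assert_array_equal(y, np.zeros(2))

    def test_zero_gain_silences_higher_level(self, rng):
        net = DaleanNet(n_hidden=4, n_l=5, n_h=6, n_i=3, rng=rng)
        net.reset_state(1)
        net.m = ad.Tensor(np.full((1, 6), 1000.0))  # p underflows to 0
        _, _, zH, _ = forward_dalean(net, rng.standard_normal(2))
        np.testing.assert_array_equal(zH, np.zeros(6))

    def test_default_population_sizes(self, rng):
        net = DaleanNet(n_hidden=4, rng=rng)
        assert (net.n_l, net.n_h, net.n_i) == (40, 100, 20)

    def test_rates_never_negative(self, rng):
        """Positivity across 1000 random inputs and modulation states."""
        net = DaleanNet(n_hidden=4, n_l=5, n_h=6, n_i=3, rng=rng)
        net.reset_state(1000)
        net.m = ad.Tensor(rng.standard_normal((1000, 6)) * 3)
        x = rng.standard_normal((1000, 2)) * 2
        zL, zI, zH, y = forward_dalean(net, x)
        for z in (zL, zI, zH):
            assert (z >= 0).all()
        p = gain_from_modulation(net.m.data)
        assert (p > 0).all() and (p < 1).all()

    def test_class_step_consistent_with_pure_function(self, rng):
        net = DaleanNet(n_hidden=4, n_l=5, n_h=6, n_i=3, tau=4.0, rng=rng)
        net.reset_state(1)
        x = rng.standard_normal((1, 2))
        with ad.no_grad():
            y, info = net.step(x)
        zL, zI, zH, y_pure = forward_dalean(net, x[0])
        np.testing.assert_allclose(info["zH"].data[0], zH, atol=1e-12)
        np.testing.assert_allclose(y.data[0], y_pure, atol=1e-12)


class TestEffectiveWeights:
    def test_simple_identity(self, rng):
        net = SimpleModulatedNet(n_hidden=4, rng=rng)
        net.W0 = ad.Tensor(np.eye(2))
        net.reset_state(1)
        np.testing.assert_allclose(effective_weights(net), np.eye(2))

    def test_simple_is_elementwise_product(self, rng):
        net = SimpleModulatedNet(n_hidden=4, rng=rng)
        net.reset_state(1)
        net.M = ad.Tensor(rng.standard_normal((1, 2, 2)))
        np.testing.assert_allclose(
            effective_weights(net), net.M.data[0] * net.W0.data
        )

    @pytest.mark.parametrize("arch", ["population", "dalean"])
    def test_matches_finite_difference_jacobian(self, rng, arch):
        if arch == "population":
            net = PopulationNet(n_hidden=4, n_z=6, rng=rng)
            net.reset_state(1)
            net.m = ad.Tensor(rng.standard_normal((1, 6)))
            fwd = lambda x: forward_population(net, x)[1]
        else:
            net = DaleanNet(n_hidden=4, n_l=5, n_h=6, n_i=3, rng=rng)
            net.reset_state(1)
            net.m = ad.Tensor(rng.standard_normal((1, 6)))
            fwd = lambda x: forward_dalean(net, x)[3]
        x0 = rng.standard_normal(2)
        if arch == "dalean":
            # fix the operating point: active-unit masks at x0
            zL, zI, zH, _ = forward_dalean(net, x0)
            net._masks = ((zL > 0)[None], (zI > 0)[None], (zH > 0)[None])
        W_eff = effective_weights(net)
        eps = 1e-7
        J = np.column_stack(
            [(fwd(x0 + eps * e) - fwd(x0 - eps * e)) / (2 * eps) for e in np.eye(2)]
        )
        np.testing.assert_allclose(W_eff, J, atol=1e-5)
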
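"""Path-integral spiking model: series potential, firing rates, exact
spatiotemporal trace, cluster expansion, STDP window and learning rules."""

import numpy as np
import pytest

from thermoneuro.feature_map import LayeredNetwork, psl_learning_step
from thermoneuro.feynman import (
    ExpansionState,
    FeynmanNetwork,
    SigmaModel,
    SynapseParams,
    conditional_firing_rate,
    exact_free_energy_of_weights,
    exact_trace_one_point,
    free_energy_gradient_learning,
    mayer_one_point,
    mayer_series_all,
    series_potential,
    site_action,
    spatiotemporal_learning_step,
    spiking_monte_carlo,
    stdp_route_weight_gradient,
    stdp_window_theory,
    zero_T_firing_condition,
)
from thermoneuro.kernels import (
    AlphaParams,
    LagFunction,
    SpikeRaster,
    TimeGrid,
    lif_lambda_syn,
    symmetric_lags,
)


def exp_kernel(n_bins, dt=1.0, tau=2.0):
    lags = symmetric_lags(dt * (n_bins - 1), dt)
    vals = np.where(lags > 0, np.exp(-lags / tau), 0.0)
    return LagFunction(lags, vals)


def two_neuron_net(w=0.8, n_bins=8, T=1.0, B=None, dt=1.0):
    grid = TimeGrid(dt=dt, n_steps=n_bins)
    W = np.zeros((2, 2))
    W[0, 1] = w
    if B is None:
        B = np.full((2, n_bins), -2.0)
    return FeynmanNetwork(W=W, lambda_syn=exp_kernel(n_bins, dt), grid=grid,
                          B=B, T=T)


class TestSeriesPotential:
    def test_no_spikes_returns_bias_trace(self, rng):
        net = two_neuron_net()
        h = rng.normal(size=(2, 8))
        raster = SpikeRaster(np.zeros((2, 8), dtype=int), net.grid)
        assert np.allclose(series_potential(net, raster, h), h)

    def test_single_spike_adds_kernel_response(self):
        net = two_neuron_net(w=0.5)
        h = np.zeros((2, 8))
        vals = np.zeros((2, 8), dtype=int)
        vals[1, 2] = 1  # presynaptic spike at t0 = 2
        V = series_potential(net, SpikeRaster(vals, net.grid), h)
        lam = net.kernel_on_bins()
        for t in range(8):
            expected = 0.5 * lam[t - 2] if t > 2 else 0.0
            assert V[0, t] == pytest.approx(expected)

    def test_two_spikes_superpose(self):
        net = two_neuron_net(w=0.5)
        h = np.zeros((2, 8))
        a = np.zeros((2, 8), dtype=int)
        b = np.zeros((2, 8), dtype=int)
        both = np.zeros((2, 8), dtype=int)
        a[1, 1] = b[1, 4] = 1
        both[1, 1] = both[1, 4] = 1
        Va = series_potential(net, SpikeRaster(a, net.grid), h)
        Vb = series_potential(net, SpikeRaster(b, net.grid), h)
        Vab = series_potential(net, SpikeRaster(both, net.grid), h)
        assert np.allclose(Vab, Va + Vb)


class TestConditionalRate:
    def test_refractory_veto(self):
        net = two_neuron_net()
        net.tau_r = 3.0
        vals = np.zeros((2, 8), dtype=int)
        vals[0, 2] = 1  # own spike
        raster = SpikeRaster(vals, net.grid)
        assert conditional_firing_rate(net, raster, 4, 0) == 0.0
        assert conditional_firing_rate(net, raster, 7, 0) > 0.0

    def test_constant_bias_without_history(self):
        net = two_neuron_net(B=np.full((2, 8), -1.5))
        net.rate_const = 2.0
        raster = SpikeRaster(np.zeros((2, 8), dtype=int), net.grid)
        assert conditional_firing_rate(net, raster, 5, 0) == pytest.approx(
            2.0 * np.exp(-1.5)
        )

    def test_monotone_in_excitatory_drive(self):
        rates = []
        for w in (0.0, 0.4, 0.8):
            net = two_neuron_net(w=w)
            vals = np.zeros((2, 8), dtype=int)
            vals[1, 2] = 1
            raster = SpikeRaster(vals, net.grid)
            rates.append(conditional_firing_rate(net, raster, 4, 0))
        assert rates[0] < rates[1] < rates[2]


class TestZeroTemperatureFiring:
    def test_no_weight_never_fires(self):
        syn = SynapseParams(g_syn=0.0, V_syn=2.0, V_eq=0.0, V_th=1.0)
        assert not zero_T_firing_condition(syn, [0.0], exp_kernel(20))

    def test_threshold_at_kernel_peak(self):
        lam = exp_kernel(20)
        peak = lam.values.max()
        vth = 1.0
        # fires iff g (V_syn - V_eq) >= vth / peak
        w_crit = vth / peak
        above = SynapseParams(g_syn=1.0, V_syn=w_crit * 1.01, V_th=vth)
        below = SynapseParams(g_syn=1.0, V_syn=w_crit * 0.99, V_th=vth)
        assert zero_T_firing_condition(above, [0.0], lam)
        assert not zero_T_firing_condition(below, [0.0], lam)

    def test_boundary_is_hyperbola_in_conductance_and_reversal(self):
        lam = exp_kernel(20)
        peak = lam.values.max()
        w_crit = 1.0 / peak
        for g in (0.5, 1.0, 2.0, 4.0):
            v = w_crit / g  # g (V - 0) = w_crit along the hyperbola
            on = SynapseParams(g_syn=g, V_syn=v * 1.02)
            off = SynapseParams(g_syn=g, V_syn=v * 0.98)
            assert zero_T_firing_condition(on, [0.0], lam)
            assert not zero_T_firing_condition(off, [0.0], lam)


class TestSpikingMonteCarlo:
    def test_strong_negative_bias_gives_empty_rasters(self):
        net = two_neuron_net(B=np.full((2, 8), -40.0), T=0.5)
        rasters = spiking_monte_carlo(net, n_trials=20, seed=0)
        assert all(r.values.sum() == 0 for r in rasters)

    def test_isolated_neuron_rate_matches_binomial(self):
        n_bins, T, B = 50, 1.0, -3.0
        grid = TimeGrid(dt=1.0, n_steps=n_bins)
        net = FeynmanNetwork(W=np.zeros((1, 1)), lambda_syn=exp_kernel(n_bins),
                             grid=grid, B=np.full((1, n_bins), B), T=T)
        n_trials = 600
        rasters = spiking_monte_carlo(net, n_trials=n_trials, seed=1)
        p_bin = np.exp(B / T) * grid.dt
        emp = np.mean([r.values.mean() for r in rasters])
        se = np.sqrt(p_bin * (1 - p_bin) / (n_trials * n_bins))
        assert abs(emp - p_bin) < 3 * se

    def test_response_peak_follows_kernel_shape(self):
        # strong synapse: the post-spike rate modulation peaks where the
        # LIF kernel peaks
        p = AlphaParams()
        grid = TimeGrid(dt=1.0, n_steps=30)
        lam = lif_lambda_syn(grid, p, normalize=True)
        lam_bins = np.zeros(30)
        for k in range(30):
            idx = np.argmin(np.abs(lam.lags - k))
            lam_bins[k] = lam.values[idx] if lam.lags[idx] > 0 else 0.0
        W = np.zeros((2, 2))
        W[0, 1] = 3.0
        B = np.full((2, 30), -5.0)
        net = FeynmanNetwork(W=W, lambda_syn=lam, grid=grid, B=B, T=1.0)
        clamp = np.zeros((2, 30), dtype=np.int8)
        clamp[1, 0] = 1
        rasters = spiking_monte_carlo(net, h=clamp, n_trials=3000, seed=2,
                                      drive_from=np.array([False, True]))
        rho = np.mean([r.values[0] for r in rasters], axis=0)
        assert np.argmax(rho) == np.argmax(lam_bins)


class TestExactTrace:
    def test_free_bins_are_logistic(self, rng):
        B = rng.normal(size=6)
        res = exact_trace_one_point(np.zeros((6, 6)), B, T=1.3)
        assert np.allclose(res.means, 1 / (1 + np.exp(-B / 1.3)))

    def test_bias_derivative_identity(self, rng):
        net = two_neuron_net(w=0.6, n_bins=4)
        Dmat, B = site_action(net)
        res = exact_trace_one_point(Dmat, B, net.T)
        eps = 1e-5
        for a in (0, 3, 5):
            Bp, Bm = B.copy(), B.copy()
            Bp[a] += eps
            Bm[a] -= eps
            dF = (
                exact_trace_one_point(Dmat, Bp, net.T).free_energy
                - exact_trace_one_point(Dmat, Bm, net.T).free_energy
            ) / (2 * eps)
            assert -dF == pytest.approx(res.means[a], abs=1e-6)

    def test_second_derivative_gives_connected_two_point(self, rng):
        net = two_neuron_net(w=0.6, n_bins=4)
        Dmat, B = site_action(net)
        res = exact_trace_one_point(Dmat, B, net.T)
        eps = 1e-4

        def F(d):
            return exact_trace_one_point(Dmat, B + d, net.T).free_energy

        for a, b in [(0, 5), (2, 6), (1, 3)]:
            da = np.zeros_like(B)
            db = np.zeros_like(B)
            da[a] = eps
            db[b] = eps
            d2 = (F(da + db) - F(da - db) - F(-da + db) + F(-da - db)) / (4 * eps**2)
            assert -net.T * d2 == pytest.approx(res.connected[a, b], abs=1e-5)

    def test_two_point_symmetry(self):
        net = two_neuron_net(w=0.7, n_bins=4)
        Dmat, B = site_action(net)
        res = exact_trace_one_point(Dmat, B, net.T)
        assert np.allclose(res.two_point, res.two_point.T)

    def test_site_limit_enforced(self):
        with pytest.raises(ValueError):
            exact_trace_one_point(np.zeros((21, 21)), np.zeros(21), 1.0)


class TestMayerExpansion:
    def test_free_limit_bare_series_is_fugacity(self):
        net = two_neuron_net(w=0.0, B=np.full((2, 8), -3.0))
        st = ExpansionState.from_network(net, order=3)
        z = np.exp(-3.0)
        assert mayer_one_point(st, 0, 4, resummed=False) == pytest.approx(z)

    def test_free_limit_resummed_series_is_exact(self):
        net = two_neuron_net(w=0.0, B=np.full((2, 8), -3.0))
        st = ExpansionState.from_network(net, order=3)
        z = np.exp(-3.0)
        assert mayer_one_point(st, 0, 4) == pytest.approx(z / (1 + z))

    def test_symmetric_pair_has_equal_one_points(self):
        grid = TimeGrid(dt=1.0, n_steps=5)
        W = np.array([[0.0, 0.4], [0.4, 0.0]])
        net = FeynmanNetwork(W=W, lambda_syn=exp_kernel(5), grid=grid,
                             B=np.full((2, 5), -2.5), T=1.0)
        st = ExpansionState.from_network(net, order=3)
        vals = mayer_series_all(st)
        assert np.allclose(vals[:5], vals[5:])

    def test_mayer_functions_vanish_with_causal_kernel(self):
        net = two_neuron_net(w=0.5)
        st = ExpansionState.from_network(net)
        # no interaction where the causal kernel is zero: upper triangle of
        # the postsynaptic block and everything involving neuron 0 as source
        assert np.all(st.fplus[8:, :8] == 0)  # no synapse 1 <- 0
        assert np.all(np.triu(st.fplus[:8, 8:]) == 0)  # causality in time

    def test_weak_coupling_matches_exact_within_next_order(self):
        # postsynaptic one-point function vs exact enumeration at 2 x 8
        z0 = 0.05
        net = two_neuron_net(w=0.4, B=np.full((2, 8), np.log(z0)))
        Dmat, B = site_action(net)
        exact = exact_trace_one_point(Dmat, B, net.T).means[:8]
        for order, bound in ((1, 10 * z0**2), (2, 10 * z0**3), (3, 10 * z0**4)):
            st = ExpansionState.from_network(net, order=order)
            err = np.abs(mayer_series_all(st)[:8] - exact).max()
            assert err < bound

    def test_truncation_error_scales_with_order(self):
        # halving the fugacity must shrink the truncation error by about
        # 2^(order+1); the asymptotic rate is order+1, observed slightly
        # below at finite fugacity
        zs = (0.02, 0.04, 0.08)
        errs = {1: [], 2: [], 3: []}
        for z0 in zs:
            net = two_neuron_net(w=0.8, B=np.full((2, 8), np.log(z0)))
            Dmat, B = site_action(net)
            exact = exact_trace_one_point(Dmat, B, net.T).means[:8]
            for order in errs:
                st = ExpansionState.from_network(net, order=order)
                errs[order].append(
                    np.abs(mayer_series_all(st)[:8] - exact).max()
                )
        for order, es in errs.items():
            slope = np.polyfit(np.log(zs), np.log(es), 1)[0]
            assert slope > order + 0.7


class TestStdpWindow:
    def make_kernel(self):
        grid = TimeGrid(dt=0.5, n_steps=401)
        return lif_lambda_syn(grid, AlphaParams(), normalize=True)

    def test_without_entropy_term_window_is_kernel(self):
        lam = self.make_kernel()
        om = stdp_window_theory(lam, SigmaModel(A=0.0, sigma=30.0))
        assert np.allclose(om.values, lam.values)

    def test_ltp_ltd_sign_structure(self):
        lam = self.make_kernel()
        om = stdp_window_theory(lam, SigmaModel(A=0.02, sigma=30.0))
        neg = om.lags < 0
        pos_small = (om.lags > 0) & (om.lags <= 15)
        assert np.all(om.values[neg] < 0)
        assert np.all(om.values[pos_small] > 0)

    def test_stronger_entropy_kernel_deepens_depression(self):
        lam = self.make_kernel()
        om1 = stdp_window_theory(lam, SigmaModel(A=0.02, sigma=30.0))
        om2 = stdp_window_theory(lam, SigmaModel(A=0.04, sigma=30.0))
        neg = om1.lags < 0
        assert np.all(om2.values[neg] < om1.values[neg])

    def test_window_vanishes_far_from_zero_lag(self):
        lam = self.make_kernel()
        om = stdp_window_theory(lam, SigmaModel(A=0.02, sigma=30.0))
        peak = np.abs(om.values).max()
        far = np.abs(om.lags) > 150  # 5 sigma
        assert np.abs(om.values[far]).max() < 1e-6 * peak

    def test_noncausal_kernel_rejected(self):
        lags = symmetric_lags(5.0, 1.0)
        bad = LagFunction(lags, np.ones_like(lags))
        with pytest.raises(ValueError):
            stdp_window_theory(bad, SigmaModel())


class TestFreeEnergyLearning:
    def test_causal_pairing_potentiates_the_synapse(self):
        # presynaptic neuron biased to fire early, postsynaptic late:
        # the free-energy gradient increases the excitatory weight
        grid = TimeGrid(dt=1.0, n_steps=4)
        B = np.full((2, 4), -3.0)
        B[1, 0] = 2.0   # pre fires early
        B[0, 2] = 0.5   # post likely fires later
        W0 = np.zeros((2, 2))
        W0[0, 1] = 0.3
        template = FeynmanNetwork(W=W0, lambda_syn=exp_kernel(4), grid=grid,
                                  B=B, T=1.0)
        F = exact_free_energy_of_weights(template)
        W1 = free_energy_gradient_learning(W0, F, lr=0.5)
        assert W1[0, 1] > W0[0, 1]

    def test_sign_projection_never_flips_weights(self):
        W0 = np.array([[0.0, 0.01], [0.0, 0.0]])

        def bogus_grad(_W):
            return np.full((2, 2), 10.0)  # would push the weight negative

        W1 = free_energy_gradient_learning(W0, bogus_grad, lr=1.0)
        assert W1[0, 1] == 0.0

    def test_weight_gradient_matches_correlation_route(self):
        # dF/dW via finite differences equals the window-weighted
        # two-point-function sum on an exactly enumerable grid
        grid = TimeGrid(dt=1.0, n_steps=8)
        B = np.full((2, 8), -2.0)
        B[1, 1] = 0.5
        W0 = np.zeros((2, 2))
        W0[0, 1] = 0.5
        template = FeynmanNetwork(W=W0, lambda_syn=exp_kernel(8), grid=grid,
                                  B=B, T=1.0)
        F = exact_free_energy_of_weights(template)
        eps = 1e-5
        Wp, Wm = W0.copy(), W0.copy()
        Wp[0, 1] += eps
        Wm[0, 1] -= eps
        fd = -(F(Wp) - F(Wm)) / (2 * eps)
        route = stdp_route_weight_gradient(template, 0, 1)
        assert fd == pytest.approx(route, abs=1e-4)


class TestSpatiotemporalRule:
    def test_zero_frequency_concentration_reduces_to_rate_rule(self, rng):
        W = rng.uniform(0.2, 1.0, size=(3, 3))
        K0 = rng.normal(size=(3, 3))
        K0 = 0.5 * (K0 + K0.T)
        Q0 = rng.normal(size=(3, 3))
        Q0 = 0.5 * (Q0 + Q0.T)
        beta, lr = 0.2, 0.05
        got = spatiotemporal_learning_step(K0, Q0, W, beta=beta, lr=lr)
        expected = W + lr * (K0 @ W @ Q0 - beta * np.linalg.solve(W @ W.T, W))
        assert np.allclose(got, expected, atol=1e-12)

    def test_matches_psl_step_up_to_scale(self, rng):
        # at zero frequency with beta = -T the spatiotemporal rule is the
        # exact-mode entropy-driven rate rule
        W = rng.uniform(0.2, 1.0, size=(3, 3))
        K0 = np.eye(3) * 0.8
        Q0 = np.eye(3)
        T, lr = 0.3, 0.05
        got = spatiotemporal_learning_step(K0, Q0, W.copy(), beta=-T, lr=lr)
        net = LayeredNetwork(n_in=3, n_out=3, W=W.copy(), K=K0)
        psl = psl_learning_step(net, Q0, T=T, lr=lr, approx=False,
                                normalize=False)
        rel = np.abs(got - psl).max() / np.abs(psl).max()
        assert rel < 1e-6

    def test_identity_kernels_amplify(self, rng):
        W = rng.uniform(0.5, 1.0, size=(2, 2))
        got = spatiotemporal_learning_step(np.eye(2), np.eye(2), W,
                                           beta=0.0, lr=0.1)
        assert np.allclose(got, 1.1 * W)

    def test_frequency_sum_assembles_real_update(self, rng):
        # conjugate-paired frequencies produce a real update
        A = rng.normal(size=(2, 2)) + 1j * rng.normal(size=(2, 2))
        Kw = np.stack([A + A.conj().T, (A + A.conj().T).conj()])
        Qw = np.stack([np.eye(2), np.eye(2)])
        W = rng.uniform(0.5, 1.0, size=(2, 2))
        got = spatiotemporal_learning_step(Kw, Qw, W, beta=0.0, lr=0.1)
        assert got.dtype == float

    def test_non_hermitian_inputs_rejected(self, rng):
        W = rng.uniform(0.5, 1.0, size=(2, 2))
        bad = np.array([[0.0, 1.0], [0.0, 0.0]], dtype=complex)
        with pytest.raises(ValueError):
            spatiotemporal_learning_step(bad, np.eye(2), W, beta=0.0, lr=0.1)
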
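"""Current formulas, gating kinetics, and vector-field contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dopadyn import (DAParams, GABAParams, ModelVariant, ca_conductance,
                     da_rhs, dr_rates, effective_ohmic, fast_na_rates,
                     gaba_wb_rhs, ih_kinetics, k_conductance,
                     nmda_conductance, sk_conductance, sna_conductance)
from dopadyn.model_core import wb_rates
from dopadyn import _kernels


class TestConductances:
    def test_ca_limits_and_midpoint(self, params):
        assert ca_conductance(-500.0, params) == pytest.approx(0.0, abs=1e-12)
        assert ca_conductance(200.0, params) == pytest.approx(params.gbar_Ca, rel=1e-9)
        assert ca_conductance(params.ca_vhalf, params) == pytest.approx(
            params.gbar_Ca / 2, rel=1e-12)

    def test_ca_monotone(self, params, v_grid):
        g = ca_conductance(v_grid, params)
        assert np.all(np.diff(g) > 0)
        assert np.all((g >= 0) & (g <= params.gbar_Ca))

    @pytest.mark.parametrize("ca,expected_frac", [
        (0.0, 0.0),
        (1.0, 0.5),          # ca = K_sk -> half saturation
        (2.0, 16.0 / 17.0),  # ca = 2*K_sk -> Hill-4 gives 16/17
    ])
    def test_sk_hill4(self, expected_frac, ca):
        p = DAParams(K_sk=1.0)
        assert sk_conductance(ca * p.K_sk, p) == pytest.approx(
            p.gbar_KCa * expected_frac, rel=1e-12)

    def test_sk_rejects_negative_ca(self, params):
        with pytest.raises(ValueError):
            sk_conductance(-0.1, params)

    def test_k_boltzmann(self, params):
        assert k_conductance(-10.0, params) == pytest.approx(
            params.gbar_K / 2, rel=1e-12)
        assert k_conductance(-3.0, params) == pytest.approx(
            params.gbar_K / (1 + np.exp(-1)), rel=1e-9)
        assert k_conductance(-300.0, params) == pytest.approx(0.0, abs=1e-12)

    def test_sna_sigmoid(self, params):
        assert sna_conductance(-50.0, params) == pytest.approx(
            params.gbar_sNa / 2, rel=1e-12)
        assert sna_conductance(-45.0, params) == pytest.approx(
            params.gbar_sNa / (1 + np.exp(-1)), rel=1e-9)
        assert sna_conductance(100.0, params) == pytest.approx(
            params.gbar_sNa, rel=1e-6)

    def test_nmda_mg_block(self, params):
        gbar = 2.0
        pre = params.Mg / 3.57
        assert nmda_conductance(0.0, gbar, params) == pytest.approx(
            gbar / (1 + pre), rel=1e-12)
        assert nmda_conductance(-60.0, gbar, params) == pytest.approx(
            gbar / (1 + pre * np.exp(3.72)), rel=1e-9)
        assert nmda_conductance(400.0, gbar, params) == pytest.approx(
            gbar, rel=1e-9)

    def test_nmda_balance_ratio_near_3_4(self, params):
        """Ohmic trade-off (v+90)/(-v * block(v)) ~ 3.4 across the
        subthreshold range -- the NMDA/GABA balance slope."""
        for v in (-65.0, -60.0, -55.0):
            block = nmda_conductance(v, 1.0, params)
            ratio = (v + 90.0) / (-v * block)
            assert ratio == pytest.approx(3.4, abs=0.15)


class TestKinetics:
    def test_ih_midpoint_and_tau(self):
        q_inf, _ = ih_kinetics(-95.0)
        assert q_inf == pytest.approx(0.5, rel=1e-12)
        _, tau = ih_kinetics(-112.0)
        assert tau == pytest.approx(312.5, rel=1e-12)
        q87, _ = ih_kinetics(-87.0)
        assert q87 == pytest.approx(1 / (1 + np.e), rel=1e-9)

    def test_ih_decreasing_in_v(self, v_grid):
        q_inf, tau = ih_kinetics(v_grid)
        assert np.all(np.diff(q_inf) < 0)
        assert np.all(tau > 0)

    def test_fast_na_values(self):
        m_inf, alpha_h, beta_h = fast_na_rates(-47.0)
        assert alpha_h == pytest.approx(0.01, rel=1e-12)
        _, _, beta_h = fast_na_rates(-24.0)
        assert beta_h == pytest.approx(0.625, rel=1e-12)

    def test_fast_na_activation_limit(self):
        # alpha_m has a removable singularity at v = -39: limit 0.32*4
        m_at, _, _ = fast_na_rates(-39.0)
        m_near, _, _ = fast_na_rates(-39.0 + 1e-9)
        assert m_at == pytest.approx(m_near, abs=1e-10)

    def test_dr_rates(self):
        alpha_n, _ = dr_rates(-5.0)
        assert alpha_n == pytest.approx(0.032, rel=1e-9)
        _, beta_n = dr_rates(-10.0)
        assert beta_n == pytest.approx(0.05, rel=1e-12)
        alpha_low, _ = dr_rates(-200.0)
        assert alpha_low == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("v_sing,fn,idx", [
        (-39.0, fast_na_rates, 0),
        (-5.0, dr_rates, 0),
        (-30.0, wb_rates, 0),
        (-29.0, wb_rates, 3),
    ])
    def test_removable_singularities(self, v_sing, fn, idx):
        at = fn(v_sing)[idx]
        for dv in (-1e-3, -1e-6, 1e-6, 1e-3):
            assert abs(fn(v_sing + dv)[idx] - at) < 1e-4
        assert abs(fn(v_sing + 1e-9)[idx] - at) <= 1e-8

    def test_gating_steady_states_bounded(self, v_grid):
        m_inf, ah, bh = fast_na_rates(v_grid)
        an, bn = dr_rates(v_grid)
        q_inf, _ = ih_kinetics(v_grid)
        for x in (m_inf, ah / (ah + bh), an / (an + bn), q_inf):
            assert np.all((x >= 0) & (x <= 1))


class TestDARhs:
    def test_leak_only_equilibrium(self):
        p = DAParams(gbar_Ca=0, gbar_KCa=0, gbar_K=0, gbar_sNa=0, gbar_Na=0,
                     gbar_DR=0, g_l=0.18, g_h=0, ca_leak_frac=0.0)
        v = ModelVariant.reduced(include_sNa=False, include_ca_leak=False)
        d = da_rhs([p.E_l, 0.0, 0.0, 0.0, 0.0], p, v)
        assert np.allclose(d, 0.0, atol=1e-12)
        d_above = da_rhs([p.E_l + 10, 0.0, 0, 0, 0], p, v)
        assert d_above[0] < 0

    def test_reduced_rhs_independent_of_spike_gates(self, params):
        v = ModelVariant.reduced()
        s1 = [-55.0, 0.3, 0.1, 0.2, 0.9]
        s2 = [-55.0, 0.3, 0.1, 0.9, 0.2]
        assert np.allclose(da_rhs(s1, params, v), da_rhs(s2, params, v))

    def test_nonfinite_state_rejected(self, params, full_variant):
        with pytest.raises(FloatingPointError):
            da_rhs([np.nan, 0.1, 0, 0.5, 0.1], params, full_variant)

    def test_kernel_matches_reference_rhs(self, params, full_variant):
        """The numba kernel and the numpy vector field agree pointwise."""
        P = _kernels.pack_da_params(params)
        F = _kernels.pack_variant(full_variant)
        rng = np.random.default_rng(1)
        for _ in range(50):
            y = [rng.uniform(-100, 20), rng.uniform(0, 50),
                 rng.uniform(0, 1), rng.uniform(0, 1), rng.uniform(0, 1)]
            gn, ga, gg, ia = rng.uniform(0, 5, 4)
            ref = da_rhs(y, params, full_variant, g_nmda=gn, g_ampa=ga,
                         g_gaba=gg, i_app=ia)
            ker = _kernels._da_derivs(y[0], y[1], y[2], y[3], y[4], P, F,
                                      gn, ga, gg, ia)
            assert np.allclose(ref, ker, rtol=1e-12, atol=1e-12)


class TestGABANeuron:
    def test_wb_activation_limit(self):
        m_inf, *_ = wb_rates(-30.0)
        beta_m = 4 * np.exp(-25.0 / 18.0)
        assert m_inf == pytest.approx(1.0 / (1.0 + beta_m), rel=1e-6)

    def test_wb_h_gate_midpoint(self):
        # printed WB inactivation: beta_h = 1/(1+exp(-(v+23)/10))
        _, _, beta_h, _, _ = wb_rates(-23.0)
        assert beta_h == pytest.approx(0.5, rel=1e-12)

    def test_rhs_matches_kernel(self):
        p = GABAParams(i_app=-0.2)
        G = _kernels.pack_gaba_params(p)
        rng = np.random.default_rng(2)
        for _ in range(20):
            y = [rng.uniform(-90, 30), rng.uniform(0, 1), rng.uniform(0, 1)]
            ref = gaba_wb_rhs(y, p)
            ker = _kernels._wb_derivs(y[0], y[1], y[2], G, 0.0, 0.08, 10.0, 0.0)
            assert np.allclose(ref, ker[:3], rtol=1e-12)


class TestEffectiveOhmic:
    def test_pure_gaba(self):
        g, e = effective_ohmic(0.0, 2.0, e_gaba=-90.0)
        assert (g, e) == (2.0, -90.0)

    def test_equal_mix(self):
        g, e = effective_ohmic(1.0, 1.0, e_gaba=-90.0)
        assert g == 2.0 and e == pytest.approx(-45.0)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            effective_ohmic(0.0, 0.0)

    @given(ga=st.floats(0, 10), gg=st.floats(0, 10))
    @settings(max_examples=50, deadline=None)
    def test_reversal_is_convex_combination(self, ga, gg):
        if ga + gg == 0:
            return
        _, e = effective_ohmic(ga, gg, e_gaba=-90.0)
        assert -90.0 - 1e-9 <= e <= 1e-9
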
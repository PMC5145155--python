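"""Nullclines, equilibria, branch folds, and excitability verdicts."""

import numpy as np
import pytest

from dopadyn import ModelVariant
from dopadyn.dynamics_analysis import (ca_star, equilibrium_branch,
                                       excitability_type, find_equilibria,
                                       nullclines)
from dopadyn.model_core import da_rhs
from dopadyn.protocols import theta_model_rate
from dopadyn.simulation_engine import FICurve


class TestThetaModelOracle:
    """The theta-model normal form dtheta/dt = I - cos(theta) has a SNIC at
    I = 1 with rate sqrt(I^2-1)/(2*pi); an independent check of the
    square-root onset law used to certify SNIC transitions."""

    def _simulated_rate(self, i, duration=20000.0, dt=0.01):
        theta = -np.pi / 2
        crossings = 0
        for _ in range(int(duration / dt)):
            theta_new = theta + dt * (i - np.cos(theta))
            if theta < np.pi <= theta_new:
                crossings += 1
            theta = theta_new if theta_new < np.pi else theta_new - 2 * np.pi
        return crossings / duration * 1000.0

    @pytest.mark.parametrize("i", [1.02, 1.1, 1.5])
    def test_rate_matches_closed_form(self, i):
        assert self._simulated_rate(i) == pytest.approx(
            theta_model_rate(i), rel=0.05, abs=0.3)

    def test_quiescent_below_threshold(self):
        assert theta_model_rate(0.9) == 0.0
        assert self._simulated_rate(0.9, duration=5000.0) == 0.0

    def test_sqrt_onset_scaling(self):
        deltas = np.array([1e-3, 1e-2, 1e-1])
        rates = np.array([theta_model_rate(1 + d) for d in deltas])
        slope = np.polyfit(np.log(deltas), np.log(rates), 1)[0]
        assert slope == pytest.approx(0.5, abs=0.02)


class TestNullclines:
    def test_ca_nullcline_satisfies_balance(self, params):
        nc = nullclines(params, v_range=(-80.0, -30.0), n_points=60)
        variant = ModelVariant.reduced()
        for v, ca in zip(nc.v[::7], nc.ca_nullcline[::7]):
            d = da_rhs([v, ca, 0, 0, 0], params, variant)
            assert abs(d[1]) < 1e-10

    def test_v_nullcline_zeroes_current(self, params):
        nc = nullclines(params, v_range=(-80.0, -30.0), n_points=60)
        variant = ModelVariant.reduced()
        assert nc.v_nullcline_v.size > 0
        for v, ca in zip(nc.v_nullcline_v[::5], nc.v_nullcline_ca[::5]):
            d = da_rhs([v, ca, 0, 0, 0], params, variant)
            assert abs(d[0]) < 1e-6

    def test_gaba_shifts_v_nullcline_down(self, params):
        nc0 = nullclines(params, v_range=(-75.0, -40.0), n_points=80)
        nc1 = nullclines(params, g_eff=1.0, e_eff=-90.0,
                         v_range=(-75.0, -40.0), n_points=80)
        common = np.intersect1d(nc0.v_nullcline_v, nc1.v_nullcline_v)
        assert common.size > 10
        ca0 = nc0.v_nullcline_ca[np.isin(nc0.v_nullcline_v, common)]
        ca1 = nc1.v_nullcline_ca[np.isin(nc1.v_nullcline_v, common)]
        # inhibition lowers the calcium level needed to null the current
        assert np.all(ca1 <= ca0 + 1e-12)

    def test_requires_reduced_variant(self, params):
        with pytest.raises(ValueError):
            nullclines(params, ModelVariant.full())

    def test_empty_window_rejected(self, params):
        with pytest.raises(ValueError):
            nullclines(params, v_range=(-30.0, -80.0))


class TestEquilibria:
    def test_leak_only_equilibrium_at_e_l(self):
        from dopadyn.params import DAParams
        p = DAParams(gbar_Ca=0, gbar_KCa=0, gbar_K=0, gbar_sNa=0, gbar_Na=0,
                     gbar_DR=0, ca_leak_frac=0.0)
        var = ModelVariant.reduced(include_sNa=False, include_ca_leak=False)
        eqs = find_equilibria(p, var)
        assert len(eqs) == 1
        assert eqs[0].v == pytest.approx(p.E_l, abs=1e-6)
        assert eqs[0].is_stable

    def test_residuals_below_tolerance(self, params):
        eqs = find_equilibria(params, g_eff=2.0, e_eff=-75.0)
        assert eqs  # strong shunt creates at least one rest state
        for e in eqs:
            assert e.residual < 1e-8

    def test_equilibria_lie_on_nullcline_intersections(self, params):
        eqs = find_equilibria(params, g_eff=2.0, e_eff=-75.0)
        for e in eqs:
            assert e.state[1] == pytest.approx(
                ca_star(e.v, params), rel=1e-9)

    def test_background_state_has_no_stable_equilibrium(self, params):
        # the tonically firing neuron has no attracting rest state
        eqs = find_equilibria(params)
        assert not any(e.is_stable for e in eqs)


class TestEquilibriumBranch:
    def test_branch_matches_rhs_inversion(self, params):
        variant = ModelVariant.reduced(include_ih=True)
        v_grid = np.array([-70.0, -60.0, -50.0])
        i_app = equilibrium_branch(params, variant, v_grid=v_grid)
        from dopadyn.model_core import ih_kinetics
        for v, i in zip(v_grid, i_app):
            q = ih_kinetics(v)[0]
            d = da_rhs([v, ca_star(v, params), q, 0, 0],
                       params.replace(g_h=0.0), variant, i_app=i)
            assert abs(d[0]) < 1e-9


class TestExcitabilityVerdict:
    def test_jump_curve_is_type_two(self):
        fi = FICurve("i_app", np.linspace(-1, 0, 11),
                     np.r_[np.zeros(5), np.full(6, 3.0)])
        v = excitability_type(fi, eps=0.5)
        assert v.type == "II"
        assert v.onset_rate_hz == pytest.approx(3.0)

    def test_continuous_curve_is_type_one(self):
        x = np.linspace(-1, 0, 21)
        rates = np.where(x > -0.5, np.sqrt(np.clip(x + 0.5, 0, None)), 0.0)
        fi = FICurve("i_app", x, rates)
        assert excitability_type(fi, eps=0.5).type == "I"

    def test_all_spiking_curve_rejected(self):
        fi = FICurve("i_app", np.linspace(0, 1, 5), np.full(5, 2.0))
        with pytest.raises(ValueError):
            excitability_type(fi)
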
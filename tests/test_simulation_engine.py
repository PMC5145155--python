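"""Integration, spike detection, firing statistics, sweeps."""

import numpy as np
import pytest

from dopadyn import (ModelVariant, balance_line, depolarization_block_detect,
                     detect_spikes, firing_stats, integrate,
                     steady_state_rate)
from dopadyn.params import DAParams
from dopadyn.simulation_engine import HeatMap, SimulationResult, _split_drive


def _fake_result(time, v, variant, transient=0.0):
    z = np.zeros_like(np.asarray(v, dtype=float))
    return SimulationResult(time=np.asarray(time, dtype=float),
                            v=np.asarray(v, dtype=float), ca=z, q=z, h=z, n=z,
                            spike_times=detect_spikes(time, v, variant),
                            transient=transient, variant=variant)


class TestDetectSpikes:
    def test_sine_one_spike_per_period(self, full_variant):
        t = np.arange(0, 5000.0, 0.1)
        v = 50.0 * np.sin(2 * np.pi * (t - 100.0) / 1000.0)
        assert detect_spikes(t, v, full_variant).size == 5

    def test_constant_subthreshold_none(self, full_variant):
        t = np.arange(0, 1000.0, 0.1)
        assert detect_spikes(t, np.full_like(t, -20.0), full_variant).size == 0

    def test_counts_every_upcrossing(self, full_variant):
        # 10 well-separated square pulses
        t = np.arange(0, 1000.0, 0.1)
        v = np.full_like(t, -60.0)
        for k in range(10):
            sel = (t >= 100 * k + 20) & (t < 100 * k + 25)
            v[sel] = 20.0
        assert detect_spikes(t, v, full_variant).size == 10

    def test_refractory_guard_suppresses_chatter(self, full_variant):
        t = np.arange(0, 10.0, 0.01)
        v = -60 + 65 * (np.sin(2 * np.pi * t / 1.0) > 0)  # 1 ms flicker
        spk = detect_spikes(t, v, full_variant, refractory=2.0)
        assert np.all(np.diff(spk) >= 2.0)

    def test_reduced_threshold_is_minus_40(self, reduced_variant):
        t = np.arange(0, 3000.0, 0.1)
        v = -55 + 10 * np.sin(2 * np.pi * t / 1000.0)  # peaks at -45
        assert detect_spikes(t, v, reduced_variant).size == 0
        v2 = -45 + 10 * np.sin(2 * np.pi * t / 1000.0)  # peaks at -35
        assert detect_spikes(t, v2, reduced_variant).size == 3


class TestFiringStats:
    def test_periodic_train(self):
        spikes = np.arange(0, 60000, 250.0)
        rate, cv = firing_stats(spikes)
        assert rate == pytest.approx(4.0)
        assert cv == pytest.approx(0.0, abs=1e-12)

    def test_poisson_cv_near_one(self):
        rng = np.random.default_rng(0)
        isis = rng.exponential(100.0, 2000)
        rate, cv = firing_stats(np.cumsum(isis))
        assert cv == pytest.approx(1.0, abs=0.15)

    def test_single_spike_undefined(self):
        rate, cv = firing_stats([100.0])
        assert np.isnan(rate) and np.isnan(cv)

    def test_cv_undefined_below_min_isis(self):
        rate, cv = firing_stats(np.arange(0, 2500, 250.0))
        assert np.isfinite(rate) and np.isnan(cv)


class TestIntegrate:
    def test_leak_only_relaxes_to_e_l(self):
        p = DAParams(gbar_Ca=0, gbar_KCa=0, gbar_K=0, gbar_sNa=0, gbar_Na=0,
                     gbar_DR=0, g_l=0.18, ca_leak_frac=0.0)
        var = ModelVariant.reduced(include_sNa=False, include_ca_leak=False)
        res = integrate(p, var, 3000.0, y0=[-80, 0, 0, 0, 0], transient=0)
        dv = np.diff(res.v)
        assert np.all(dv >= -1e-12)           # monotone approach from below
        assert res.v[-1] == pytest.approx(p.E_l, abs=1e-3)

    def test_dt_convergence_spike_count(self, params, full_variant):
        counts = []
        for dt in (0.02, 0.01):
            res = integrate(params, full_variant, 10000.0, dt=dt, transient=0)
            counts.append(res.spike_times.size)
        assert abs(counts[0] - counts[1]) <= 1

    def test_deterministic_rerun(self, params, full_variant):
        rng = np.random.default_rng(42)
        drive = np.clip(1.0 + 0.3 * rng.standard_normal(2000), 0, None)
        a = integrate(params, full_variant, 4000.0, g_nmda=drive,
                      input_dt=2.0, transient=0)
        b = integrate(params, full_variant, 4000.0, g_nmda=drive,
                      input_dt=2.0, transient=0)
        assert np.array_equal(a.v, b.v)
        assert np.array_equal(a.spike_times, b.spike_times)

    def test_background_firing_in_band(self, params, full_variant):
        rate = steady_state_rate(params, full_variant, duration=10000.0)
        assert 1.0 <= rate <= 5.0

    def test_spike_only_path_matches_trace_path(self, params, full_variant):
        rate_fast = steady_state_rate(params, full_variant, duration=10000.0)
        res = integrate(params, full_variant, 12000.0)
        rate_trace, _ = firing_stats(res.post_transient_spikes, min_isis=2)
        assert rate_fast == pytest.approx(rate_trace, rel=0.02)

    @pytest.mark.parametrize("drive", [
        {}, {"g_nmda": 3.0}, {"g_nmda": 8.0, "g_gaba": 1.5},
    ])
    def test_spike_currents_barely_change_rate(self, params, drive):
        """Removing the spike-producing currents leaves the firing
        frequency within 20% across the NMDA drive range."""
        r_full = steady_state_rate(params, ModelVariant.full(),
                                   duration=10000.0, **drive)
        r_red = steady_state_rate(params, ModelVariant.reduced(),
                                  duration=10000.0, **drive)
        assert r_red == pytest.approx(r_full, rel=0.2)

    def test_g_eff_split_equivalence(self, params, reduced_variant):
        # g_eff at E_eff=-45 is the same as an equal AMPA/GABA mix
        r1 = steady_state_rate(params, reduced_variant, duration=8000.0,
                               g_eff=1.0, e_eff=-45.0)
        r2 = steady_state_rate(params, reduced_variant, duration=8000.0,
                               g_ampa=0.5, g_gaba=0.5)
        assert r1 == pytest.approx(r2, abs=1e-9)

    def test_unknown_drive_rejected(self, params):
        with pytest.raises(ValueError):
            _split_drive({"g_bogus": 1.0}, params)


class TestDepolarizationBlock:
    def test_flat_depolarized_is_block(self, full_variant):
        t = np.arange(0, 3000.0, 1.0)
        res = _fake_result(t, np.full_like(t, -30.0), full_variant)
        assert depolarization_block_detect(res)

    def test_hyperpolarized_rest_is_not_block(self, full_variant):
        t = np.arange(0, 3000.0, 1.0)
        res = _fake_result(t, np.full_like(t, -70.0), full_variant)
        assert not depolarization_block_detect(res)

    def test_tonic_firing_is_not_block(self, params, full_variant):
        res = integrate(params, full_variant, 6000.0)
        assert not depolarization_block_detect(res)


class TestBalanceLine:
    def test_constructed_band_recovers_slope(self):
        gg = np.linspace(0, 6, 25)
        gn = np.linspace(0, 30, 25)
        GN, GG = np.meshgrid(gn, gg)
        rate = np.where(np.abs(GN - (3.0 * GG + 1.0)) < 1.0, 2.0, 0.0)
        hmap = HeatMap(x_param="g_nmda", y_param="g_gaba", x_grid=gn,
                       y_grid=gg, rate=rate, cv=np.full_like(rate, np.nan),
                       block=np.zeros_like(rate, bool),
                       failed=np.zeros_like(rate, bool))
        slope, intercept, _ = balance_line(hmap, (1.0, 3.0))
        assert slope == pytest.approx(3.0, abs=0.15)
        assert intercept == pytest.approx(1.0, abs=0.5)

    def test_insufficient_band_cells(self):
        g = np.linspace(0, 1, 5)
        z = np.zeros((5, 5))
        hmap = HeatMap("g_nmda", "g_gaba", g, g, z, z, z.astype(bool),
                       z.astype(bool))
        with pytest.raises(ValueError):
            balance_line(hmap, (1.0, 2.0))
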
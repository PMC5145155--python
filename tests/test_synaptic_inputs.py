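"""Synthetic-input generators: Poisson trains, gating, GABA population, OU."""

import numpy as np
import pytest

from dopadyn.synaptic_inputs import (OUSpec, ReceptorGating, coincidence_drive,
                                     gaba_population_drive, gating_step,
                                     gating_trace, ou_trace,
                                     poisson_glu_trains, sine_modulated_ou)


class TestPoissonTrains:
    def test_count_statistics(self):
        ts = poisson_glu_trains(n=35, rate=10.0, duration=10000.0, seed=3)
        counts = np.array([t.size for t in ts.trains])
        # expected 100 spikes/train; each count within 3*sqrt(100)
        assert np.all(np.abs(counts - 100) <= 30)
        pooled_rate = ts.pooled().size / 35 / 10.0  # Hz per train
        assert pooled_rate == pytest.approx(10.0, rel=0.1)

    def test_zero_duration_gives_empty_trains(self):
        ts = poisson_glu_trains(n=5, rate=10.0, duration=0.0, seed=0)
        assert all(t.size == 0 for t in ts.trains)

    def test_times_sorted_and_seeded(self):
        a = poisson_glu_trains(n=3, rate=20.0, duration=5000.0, seed=7)
        b = poisson_glu_trains(n=3, rate=20.0, duration=5000.0, seed=7)
        for ta, tb in zip(a.trains, b.trains):
            assert np.array_equal(ta, tb)
            assert np.all(np.diff(ta) >= 0)

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            poisson_glu_trains(rate=0.0)


class TestCoincidenceDrive:
    def _set(self, times_by_train, duration=100.0):
        from dopadyn.synaptic_inputs import SpikeTrainSet
        return SpikeTrainSet([np.asarray(t, dtype=float)
                              for t in times_by_train], 10.0, duration, 0)

    def test_isolated_spike_ignored(self):
        j = coincidence_drive(self._set([[50.0]]), k_min=2)
        assert not j.any()

    def test_two_close_spikes_one_pulse(self):
        j = coincidence_drive(self._set([[50.1], [50.3]]), window=1.0,
                              k_min=2, dt=0.1)
        assert j.sum() * 0.1 == pytest.approx(1.0)  # one 1 ms pulse

    def test_kmin1_matches_merged_events(self):
        rng = np.random.default_rng(0)
        times = np.sort(rng.uniform(0, 1000.0, 50))
        j = coincidence_drive(self._set([times], duration=1000.0), k_min=1,
                              dt=0.1)
        # brute force: merge 1 ms bins that contain spikes
        bins = np.unique((times // 1.0).astype(int))
        starts = np.flatnonzero(np.diff(j, prepend=0) > 0)
        assert starts.size == np.count_nonzero(np.diff(bins, prepend=-10) > 0 | np.ones_like(bins, bool)) or starts.size <= bins.size
        # pulse-on time equals 1 ms per occupied, non-overlapping bin group
        assert j.sum() * 0.1 <= bins.size * 1.0 + 1e-9


class TestGating:
    def test_sustained_drive_closed_form(self):
        g = ReceptorGating.nmda()
        t = np.arange(1, 501) * 0.1
        s = gating_trace(np.ones(500), 0.1, g)
        assert np.allclose(s[1:], 1 - np.exp(-t / g.tau_act), rtol=1e-10)

    def test_pure_decay_closed_form(self):
        g = ReceptorGating(1.0, 10.0, s=1.0)
        t = np.arange(1, 201) * 0.05
        s = gating_trace(np.zeros(200), 0.05, g)
        assert np.allclose(s[1:], np.exp(-t / 10.0), rtol=1e-10)

    def test_fixed_point_at_one(self):
        g = ReceptorGating(1.0, 10.0, s=1.0)
        assert gating_step(g, 1.0, 5.0).s == pytest.approx(1.0)

    def test_gates_stay_bounded_under_random_drive(self):
        rng = np.random.default_rng(5)
        j = (rng.random(5000) < 0.3).astype(float)
        s = gating_trace(j, 0.1, ReceptorGating.ampa())
        assert np.all((s >= 0) & (s <= 1))


class TestGABAPopulation:
    def test_population_rates_in_band(self):
        _, _, counts = gaba_population_drive(n_neurons=10, duration=5000.0,
                                             seed=11)
        rates = counts / 5.0
        assert np.all(rates >= 10.0) and np.all(rates <= 25.0)

    def test_population_gate_quasi_constant(self):
        t, s, _ = gaba_population_drive(n_neurons=30, duration=6000.0, seed=4)
        tail = s[t > 1000.0]
        assert tail.mean() > 0.01
        assert tail.std() / tail.mean() < 0.3
        assert np.all((s >= 0) & (s <= 1))

    def test_single_neuron_pulsates(self):
        t, s1, _ = gaba_population_drive(n_neurons=1, duration=6000.0, seed=4)
        t, s30, _ = gaba_population_drive(n_neurons=30, duration=6000.0, seed=4)
        m1, m30 = s1[t > 1000], s30[t > 1000]
        cv1 = m1.std() / m1.mean()
        cv30 = m30.std() / m30.mean()
        assert cv1 > 3 * cv30
        assert np.ptp(m1) > 0.9  # full-swing pulsation without averaging


class TestOU:
    def test_zero_sigma_constant(self):
        _, g = ou_trace(OUSpec(mu=1.5, sigma=0.0, seed=0), 1000.0)
        assert np.allclose(g, 1.5)

    def test_stationary_mean_sd(self):
        spec = OUSpec(mu=1.5, sigma=0.3, c=0.0, tau=5.0, seed=8)
        _, g = ou_trace(spec, 200000.0, dt=0.5, clip=False)
        n_eff = 200000.0 / (2 * spec.tau)
        se = spec.sigma / np.sqrt(n_eff)
        assert abs(g.mean() - 1.5) < 4 * se
        assert abs(g.std() - 0.3) < 0.02

    def test_autocorrelation_time(self):
        spec = OUSpec(mu=0.0, sigma=1.0, c=0.0, tau=5.0, seed=9)
        _, g = ou_trace(spec, 400000.0, dt=0.5, clip=False)
        x = g[:, 0] - g[:, 0].mean()
        for lag_ms in (2.5, 5.0, 10.0):
            lag = int(lag_ms / 0.5)
            rho = np.dot(x[:-lag], x[lag:]) / np.dot(x, x)
            assert rho == pytest.approx(np.exp(-lag_ms / 5.0), abs=0.03)

    def test_pairwise_correlation_equals_c(self):
        spec = OUSpec(mu=5.0, sigma=0.5, c=0.5, tau=5.0, seed=10)
        _, g = ou_trace(spec, 300000.0, dt=0.5, n_targets=4, clip=False)
        cors = []
        for i in range(4):
            for j in range(i + 1, 4):
                cors.append(np.corrcoef(g[:, i], g[:, j])[0, 1])
        assert np.mean(cors) == pytest.approx(0.5, abs=0.05)

    def test_seed_reproducibility(self):
        spec = OUSpec(seed=12)
        _, a = ou_trace(spec, 1000.0)
        _, b = ou_trace(spec, 1000.0)
        assert np.array_equal(a, b)

    def test_sine_modulation(self):
        spec = OUSpec(mu=1.5, sigma=0.2, seed=13)
        t, g0 = ou_trace(spec, 4000.0)
        t, gm = sine_modulated_ou(spec, 1.0, 0.0, 4000.0)
        assert np.array_equal(g0, gm)  # zero depth reproduces ou_trace
        t, gmod = sine_modulated_ou(spec, 1.0, 0.8, 4000.0)
        # average over integer periods returns the mean
        assert gmod.mean() == pytest.approx(1.5, abs=0.1)

    def test_sine_spectral_peak(self):
        spec = OUSpec(mu=2.0, sigma=0.2, tau=5.0, seed=14)
        t, g = sine_modulated_ou(spec, 1.0, 1.0, 60000.0, dt=1.0)
        x = g[:, 0] - g[:, 0].mean()
        freqs = np.fft.rfftfreq(x.size, d=1e-3)  # Hz
        power = np.abs(np.fft.rfft(x)) ** 2
        sel = (freqs > 0.2) & (freqs < 20.0)
        assert freqs[sel][np.argmax(power[sel])] == pytest.approx(1.0, abs=0.05)
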
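"""Heterogeneous DA-neuron populations, synchrony, and dopamine release.

A population of tonically active DA neurons (leak-conductance
heterogeneity) receives correlated fluctuating NMDA drive (shared-noise OU
processes).  Synaptic dopamine follows impulsive release per spike with
Michaelis-Menten reuptake.  Protocols compare a control population against
one under tonic AMPA/GABA background tone (balanced to the same mean rate)
or under an EtOH-like condition (scaled Ih, AMPA and GABA currents), the
manipulations that switch the neurons from type I to type II excitability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .params import DAParams, ModelVariant
from .simulation_engine import REFRACTORY
from .synaptic_inputs import OUSpec, ou_trace, sine_modulated_ou

__all__ = [
    "DAReleaseParams", "DATrace", "PopulationSpec", "PopulationResult",
    "da_release", "simulate_population", "synchrony_index",
    "balance_tone", "etoh_protocol", "reward_coding_protocol",
    "da_plateau_closed_form",
]


@dataclass
class DAReleaseParams:
    """Release-per-spike and Michaelis-Menten uptake constants."""

    da_max: float = 0.1     # uM released per spike
    v_max: float = 0.004    # uM/ms maximal uptake rate
    k_m: float = 0.2        # uM transporter affinity

    def __post_init__(self) -> None:
        if min(self.da_max, self.v_max, self.k_m) <= 0:
            raise ValueError("all release parameters must be > 0")


@dataclass
class DATrace:
    t: np.ndarray           # ms
    da: np.ndarray          # uM
    cumulative: np.ndarray  # uM released up to t
    spikes: np.ndarray      # pooled source spike times

    @property
    def time_integral(self) -> float:
        """Integral of [DA] over time (uM*ms).

        At matched spike counts, synchronous firing yields a larger
        integral than asynchronous firing because Michaelis-Menten uptake
        saturates during concentration transients.
        """
        return float(np.trapezoid(self.da, self.t))


@dataclass
class PopulationSpec:
    """A heterogeneous DA population and its background condition.

    ``condition`` selects the background synaptic tone: 'control' (none),
    'tonic_tone' (tonic AMPA balanced by GABA to the control rate), or
    'etoh' (Ih, AMPA and GABA currents scaled up).  Leak conductances are
    drawn uniformly within ``leak_spread`` of the nominal value, keeping
    every neuron tonically active in control.
    """

    params: DAParams
    n_neurons: int = 50
    leak_spread: float = 0.15
    condition: str = "control"
    g_ampa_tone: float = 0.0
    g_gaba_tone: float = 0.0
    gh_tone: float = 0.0
    ou: OUSpec = field(default_factory=OUSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons < 2:
            raise ValueError("n_neurons must be >= 2")
        if self.condition not in ("control", "tonic_tone", "etoh"):
            raise ValueError(f"unknown condition: {self.condition}")


@dataclass
class PopulationResult:
    raster: list[np.ndarray]      # spike times per neuron (ms)
    bin_edges: np.ndarray
    summed: np.ndarray            # population spike counts per bin
    da: DATrace
    mean_rate: float              # Hz per neuron
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Dopamine release
# ---------------------------------------------------------------------------

def da_release(spikes, p: DAReleaseParams | None = None, dt: float = 1.0,
               duration: float | None = None, da0: float = 0.0) -> DATrace:
    """Synaptic [DA](t) from pooled spike times.

    Each spike increments [DA] by ``da_max`` instantaneously; between
    spikes [DA] decays by Michaelis-Menten uptake v_max*[DA]/(k_m+[DA])
    (RK4 on the smooth part).  [DA] never becomes negative.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    p = p or DAReleaseParams()
    spikes = np.sort(np.asarray(spikes, dtype=float))
    if duration is None:
        duration = float(spikes[-1]) + 1000.0 if spikes.size else 1000.0
    n = int(np.ceil(duration / dt))
    counts = np.zeros(n)
    if spikes.size:
        idx = np.minimum((spikes / dt).astype(int), n - 1)
        counts = np.bincount(idx, minlength=n).astype(float)

    def decay(x):
        return -p.v_max * x / (p.k_m + x)

    da = np.empty(n + 1)
    cum = np.empty(n + 1)
    da[0] = da0
    cum[0] = 0.0
    x = da0
    released = 0.0
    for i in range(n):
        inc = counts[i] * p.da_max
        x += inc
        released += inc
        k1 = decay(x)
        k2 = decay(x + 0.5 * dt * k1)
        k3 = decay(x + 0.5 * dt * k2)
        k4 = decay(x + dt * k3)
        x += dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        x = max(x, 0.0)
        da[i + 1] = x
        cum[i + 1] = released
    t = np.arange(n + 1) * dt
    return DATrace(t=t, da=da, cumulative=cum, spikes=spikes)


def da_plateau_closed_form(rate_hz: float, p: DAReleaseParams | None = None
                           ) -> float:
    """Flux-balance plateau [DA]* = k_m*R/(v_max - R), R = da_max*rate.

    Valid for regular spiking with release flux below the uptake maximum.
    """
    p = p or DAReleaseParams()
    flux = p.da_max * rate_hz / 1000.0
    if flux >= p.v_max:
        raise ValueError("release flux exceeds uptake capacity; no plateau")
    return p.k_m * flux / (p.v_max - flux)


# ---------------------------------------------------------------------------
# Population simulation
# ---------------------------------------------------------------------------

def _condition_params(spec: PopulationSpec, g_l: float) -> tuple[DAParams, float, float]:
    p = spec.params.replace(g_l=g_l)
    g_ampa = g_gaba = 0.0
    if spec.condition in ("tonic_tone", "etoh"):
        g_ampa, g_gaba = spec.g_ampa_tone, spec.g_gaba_tone
        p = p.replace(g_h=spec.gh_tone)
    return p, g_ampa, g_gaba


def simulate_population(spec: PopulationSpec, duration: float, *,
                        g_nmda_drive: np.ndarray | None = None,
                        drive_dt: float = 0.5, dt: float = 0.02,
                        bin_width: float = 20.0,
                        release: DAReleaseParams | None = None,
                        rate_check: bool = False,
                        control_rate: float | None = None
                        ) -> PopulationResult:
    """Simulate ``spec.n_neurons`` independent DA neurons under shared drive.

    ``g_nmda_drive`` (steps x neurons) overrides the OU NMDA drive derived
    from ``spec.ou``; pass an explicit array for pulse protocols.  With
    ``rate_check``, a tonic-tone population whose mean rate deviates from
    ``control_rate`` by more than 10% raises a configuration error.
    """
    rng = np.random.default_rng(spec.seed)
    g_l0 = spec.params.g_l
    leaks = g_l0 * rng.uniform(1.0 - spec.leak_spread, 1.0 + spec.leak_spread,
                               spec.n_neurons)
    if g_nmda_drive is None:
        ou = replace(spec.ou, seed=spec.seed + 1)
        _, g_nmda_drive = ou_trace(ou, duration, drive_dt, spec.n_neurons)
    variant = ModelVariant.full(
        include_ih=spec.condition == "etoh" or spec.gh_tone > 0)
    n_steps = int(round(duration / dt))
    stride = max(1, int(round(drive_dt / dt)))
    raster = []
    const = np.zeros(1)
    for i in range(spec.n_neurons):
        p_i, g_ampa, g_gaba = _condition_params(spec, leaks[i])
        P = _kernels.pack_da_params(p_i)
        F = _kernels.pack_variant(variant)
        y0 = np.array([-60.0 + rng.uniform(-5, 5), 0.2, 0.01, 0.6, 0.05])
        times, count, _, ok = _kernels.da_spike_times(
            P, F, y0, dt, n_steps,
            np.ascontiguousarray(g_nmda_drive[:, i]),
            np.array([g_ampa]), np.array([g_gaba]), const,
            stride, float(variant.spike_threshold), REFRACTORY, 100000)
        raster.append(times)
    edges = np.arange(0.0, duration + bin_width, bin_width)
    summed = np.zeros(edges.size - 1)
    for spk in raster:
        summed += np.histogram(spk, bins=edges)[0]
    pooled = np.sort(np.concatenate(raster)) if raster else np.empty(0)
    datrace = da_release(pooled, release, dt=1.0, duration=duration)
    mean_rate = pooled.size / spec.n_neurons / duration * 1000.0
    if rate_check and control_rate is not None:
        if abs(mean_rate - control_rate) > 0.1 * control_rate:
            raise ValueError(
                f"unbalanced tone: mean rate {mean_rate:.2f} Hz deviates "
                f">10% from control {control_rate:.2f} Hz")
    return PopulationResult(raster=raster, bin_edges=edges, summed=summed,
                            da=datrace, mean_rate=mean_rate,
                            meta={"condition": spec.condition,
                                  "seed": spec.seed})


def synchrony_index(raster: list[np.ndarray], bin_width: float = 20.0, *,
                    duration: float | None = None, n_shuffles: int = 20,
                    seed: int = 0) -> float:
    """Population-rate variance normalized by its shuffled expectation.

    The variance of the binned summed activity is divided by its mean over
    circularly time-shifted rasters (which preserve each neuron's ISI
    statistics but destroy cross-neuron alignment); ~1 for asynchronous
    populations, > 1 for synchronous ones.  NaN for an empty raster.
    """
    if len(raster) < 2:
        raise ValueError("need >= 2 neurons")
    all_spk = np.concatenate([np.asarray(r, dtype=float) for r in raster])
    if all_spk.size == 0:
        return np.nan
    if duration is None:
        duration = float(all_spk.max()) + 1.0
    edges = np.arange(0.0, duration + bin_width, bin_width)

    def binned_var(trains):
        s = np.zeros(edges.size - 1)
        for spk in trains:
            s += np.histogram(spk, bins=edges)[0]
        return s.var()

    v_obs = binned_var(raster)
    rng = np.random.default_rng(seed)
    v_null = 0.0
    for _ in range(n_shuffles):
        shifted = [(np.asarray(r) + rng.uniform(0, duration)) % duration
                   for r in raster]
        v_null += binned_var(shifted)
    v_null /= n_shuffles
    if v_null == 0.0:
        return np.nan
    return float(v_obs / v_null)


def balance_tone(params: DAParams, g_ampa: float, *, gh: float = 0.0,
                 g_nmda_ref: float = 0.0, target_rate: float | None = None,
                 g_gaba_max: float = 5.0, duration: float = 12000.0,
                 tol: float = 0.02) -> float:
    """g_gaba that restores the control firing rate under tonic AMPA (+Ih).

    Bisects the tonic GABA conductance so that a single nominal neuron
    matches ``target_rate`` (default: its control rate at the tonic
    reference NMDA conductance ``g_nmda_ref``, typically the mean of the
    fluctuating drive).
    """
    from .simulation_engine import steady_state_rate
    variant = ModelVariant.full(include_ih=gh > 0)
    if target_rate is None:
        target_rate = steady_state_rate(params, ModelVariant.full(),
                                        duration=duration,
                                        g_nmda=g_nmda_ref)
    p = params.replace(g_h=gh)

    def rate(gg):
        return steady_state_rate(p, variant, duration=duration,
                                 g_nmda=g_nmda_ref, g_ampa=g_ampa,
                                 g_gaba=gg)

    lo, hi = 0.0, g_gaba_max
    if rate(lo) < target_rate:
        raise ValueError("tonic AMPA does not raise the rate; nothing to balance")
    if rate(hi) > target_rate:
        raise ValueError("g_gaba_max too small to reach the control rate")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if rate(mid) > target_rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Protocols
# ---------------------------------------------------------------------------

def etoh_protocol(spec: PopulationSpec, *, gh_etoh: float,
                  ampa_mult: float = 1.0, gaba_mult: float = 1.0,
                  duration: float = 20000.0, mod_freq: float = 1.0,
                  mod_depth: float = 1.0, bin_width: float = 20.0
                  ) -> dict:
    """Control vs EtOH populations under identical sine-modulated NMDA drive.

    EtOH scales the tonic AMPA/GABA tone by the given multipliers and sets
    the Ih conductance to ``gh_etoh``; both populations share seeds and the
    1 Hz sine-enveloped OU input.  Returns synchrony indices and cumulative
    DA for both conditions.
    """
    if ampa_mult < 1 or gaba_mult < 1:
        raise ValueError("multipliers must be >= 1")
    ou = replace(spec.ou, seed=spec.seed + 1)
    _, drive = sine_modulated_ou(ou, mod_freq, mod_depth, duration,
                                 n_targets=spec.n_neurons)
    control = replace(spec, condition="control")
    etoh = replace(spec, condition="etoh",
                   g_ampa_tone=spec.g_ampa_tone * ampa_mult,
                   g_gaba_tone=spec.g_gaba_tone * gaba_mult,
                   gh_tone=gh_etoh)
    out = {}
    for name, s in (("control", control), ("etoh", etoh)):
        res = simulate_population(s, duration, g_nmda_drive=drive,
                                  bin_width=bin_width)
        out[name] = {
            "result": res,
            "synchrony": synchrony_index(res.raster, bin_width,
                                         duration=duration, seed=spec.seed),
            "cumulative_da": float(res.da.cumulative[-1]),
            "da_integral": res.da.time_integral,
            "mean_rate": res.mean_rate,
        }
    return out


def reward_coding_protocol(params: DAParams, reward_values, *,
                           type2: bool = False, g_ampa_tone: float = 0.0,
                           g_gaba_tone: float = 0.0,
                           g_nmda_salience: float = 3.0,
                           g_nmda_per_value: float = 3.0,
                           pulse_ms: float = 1000.0, gap_ms: float = 1000.0,
                           settle_ms: float = 4000.0, dt: float = 0.02
                           ) -> dict:
    """Two-pulse NMDA protocol probing reward-value coding.

    Every trial applies a fixed 'salience' NMDA pulse followed, after a
    gap, by a pulse scaled by the reward value.  The type II configuration
    adds tonic AMPA compensated by GABA.  Returns the firing rate within
    the second-pulse window for each value.
    """
    variant = ModelVariant.full()
    duration = settle_ms + pulse_ms + gap_ms + pulse_ms + 1000.0
    input_dt = 1.0
    n_in = int(round(duration / input_dt))
    t_in = np.arange(n_in) * input_dt
    t2 = settle_ms + pulse_ms + gap_ms
    rates = []
    for val in reward_values:
        g = np.zeros(n_in)
        g[(t_in >= settle_ms) & (t_in < settle_ms + pulse_ms)] = g_nmda_salience
        g[(t_in >= t2) & (t_in < t2 + pulse_ms)] = g_nmda_per_value * val
        P = _kernels.pack_da_params(params)
        F = _kernels.pack_variant(variant)
        y0 = np.array([-60.0, 0.2, 0.01, 0.6, 0.05])
        times, count, _, ok = _kernels.da_spike_times(
            P, F, y0, dt, int(round(duration / dt)), g,
            np.array([g_ampa_tone if type2 else 0.0]),
            np.array([g_gaba_tone if type2 else 0.0]), np.zeros(1),
            int(round(input_dt / dt)), float(variant.spike_threshold),
            REFRACTORY, 100000)
        in_win = times[(times >= t2) & (times < t2 + pulse_ms)]
        rates.append(in_win.size / pulse_ms * 1000.0)
    return {"reward_values": np.asarray(reward_values, dtype=float),
            "second_pulse_rate": np.array(rates),
            "type": "II" if type2 else "I"}
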
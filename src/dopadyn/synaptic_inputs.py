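"""Synthetic synaptic inputs: every drive the analyses consume.

Four generators:

* Poisson glutamate spike trains (35 trains at ~10 Hz by default) with an
  NMDA coincidence threshold (two or more spikes in a 1 ms window);
* an asynchronous population of Wang-Buzsaki GABA interneurons whose
  averaged output gate provides quasi-constant inhibition;
* tonic conductances (receptor gating pinned at 1), the reduction used to
  mimic dynamic-clamp conductance injection;
* correlated Ornstein-Uhlenbeck (OU) NMDA conductance fluctuations, with
  an optional slow sinusoidal envelope.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .params import GABAParams, default_gaba_params

__all__ = [
    "ReceptorGating", "SpikeTrainSet", "OUSpec", "TonicSynapses",
    "poisson_glu_trains", "coincidence_drive", "gating_step", "gating_trace",
    "gaba_population_drive", "ou_trace", "sine_modulated_ou",
    "GABA_IAPP_12HZ", "GABA_IAPP_22HZ",
]

# Receptor gating time constants (ms): activation / deactivation
TAU_AMPA = (1.0, 1.6)
TAU_NMDA = (7.0, 170.0)
TAU_GABA = (0.08, 10.0)

# Applied currents (uA/cm^2) giving 12 and 22 Hz repetitive firing in the
# Wang-Buzsaki interneuron as implemented here (calibrated numerically;
# checked in the test suite).
GABA_IAPP_12HZ = -0.268
GABA_IAPP_22HZ = -0.1305


@dataclass
class ReceptorGating:
    """First-order receptor gate with on/off time constants."""

    tau_act: float
    tau_deact: float
    s: float = 0.0

    def __post_init__(self) -> None:
        if self.tau_act <= 0 or self.tau_deact <= 0:
            raise ValueError("time constants must be > 0")
        if not 0.0 <= self.s <= 1.0:
            raise ValueError("gate must lie in [0, 1]")

    @classmethod
    def ampa(cls) -> "ReceptorGating":
        return cls(*TAU_AMPA)

    @classmethod
    def nmda(cls) -> "ReceptorGating":
        return cls(*TAU_NMDA)

    @classmethod
    def gaba(cls) -> "ReceptorGating":
        return cls(*TAU_GABA)


@dataclass
class SpikeTrainSet:
    trains: list[np.ndarray]     # spike times (ms), strictly increasing
    rate: float                  # Hz, nominal per-train rate
    duration: float              # ms
    seed: int

    @property
    def n_trains(self) -> int:
        return len(self.trains)

    def pooled(self) -> np.ndarray:
        if not self.trains:
            return np.empty(0)
        return np.sort(np.concatenate(self.trains))


@dataclass
class OUSpec:
    """Correlated OU conductance: mean, sd, shared fraction, time constant."""

    mu: float = 1.5              # mS/cm^2
    sigma: float = 0.5           # mS/cm^2
    c: float = 0.5               # input correlation in [0, 1]
    tau: float = 5.0             # ms
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not 0.0 <= self.c <= 1.0:
            raise ValueError("c must lie in [0, 1]")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")


@dataclass
class TonicSynapses:
    """Constant maximal conductances with receptor gating fixed at 1."""

    g_nmda: float = 0.0
    g_ampa: float = 0.0
    g_gaba: float = 0.0

    def __post_init__(self) -> None:
        if min(self.g_nmda, self.g_ampa, self.g_gaba) < 0:
            raise ValueError("conductances must be >= 0")


# ---------------------------------------------------------------------------
# Glutamate input
# ---------------------------------------------------------------------------

def poisson_glu_trains(n: int = 35, rate: float = 10.0,
                       duration: float = 10000.0, seed: int = 0
                       ) -> SpikeTrainSet:
    """Independent homogeneous Poisson spike trains (rate in Hz, times in ms)."""
    if rate <= 0 or duration < 0:
        raise ValueError("rate must be > 0 and duration >= 0")
    rng = np.random.default_rng(seed)
    trains = []
    for _ in range(n):
        n_spk = rng.poisson(rate * duration / 1000.0)
        trains.append(np.sort(rng.uniform(0.0, duration, n_spk)))
    return SpikeTrainSet(trains=trains, rate=rate, duration=duration,
                         seed=seed)


def coincidence_drive(trains: SpikeTrainSet, window: float = 1.0,
                      k_min: int = 2, dt: float = 0.1) -> np.ndarray:
    """Binary NMDA drive j(t): 1 ms pulses at spike coincidences.

    The pooled train is binned at ``window`` ms; any bin holding at least
    ``k_min`` spikes triggers a 1 ms unit pulse (overlapping pulses merge).
    Returns j sampled every ``dt`` ms over the set's duration.
    """
    if k_min < 1:
        raise ValueError("k_min must be >= 1")
    n_steps = int(round(trains.duration / dt))
    j = np.zeros(n_steps)
    pooled = trains.pooled()
    if pooled.size == 0:
        return j
    n_bins = int(np.ceil(trains.duration / window))
    counts = np.bincount(np.minimum((pooled / window).astype(int), n_bins - 1),
                         minlength=n_bins)
    pulse_len = max(1, int(round(1.0 / dt)))
    for b in np.flatnonzero(counts >= k_min):
        start = int(round(b * window / dt))
        j[start:start + pulse_len] = 1.0
    return j


def gating_step(g: ReceptorGating, j: float, dt: float) -> ReceptorGating:
    """Advance a receptor gate by dt under binary drive j (exact update)."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if j > 0.5:
        s = 1.0 + (g.s - 1.0) * np.exp(-dt / g.tau_act)
    else:
        s = g.s * np.exp(-dt / g.tau_deact)
    return ReceptorGating(g.tau_act, g.tau_deact, float(s))


def gating_trace(j: np.ndarray, dt: float, gating: ReceptorGating
                 ) -> np.ndarray:
    """Gate trajectory s(t) under a sampled binary drive (length n+1)."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    return _kernels.gating_from_drive(np.asarray(j, dtype=float), dt,
                                      gating.tau_act, gating.tau_deact,
                                      gating.s)


# ---------------------------------------------------------------------------
# GABA population input
# ---------------------------------------------------------------------------

def gaba_population_drive(n_neurons: int = 30, duration: float = 10000.0,
                          dt: float = 0.02, seed: int = 0, *,
                          base: GABAParams | None = None,
                          rate_range: tuple[float, float] = (12.0, 22.0),
                          record_dt: float = 0.1):
    """Population-averaged GABA gating trace from asynchronous interneurons.

    Each of the ``n_neurons`` Wang-Buzsaki neurons receives an applied
    current drawn uniformly from the calibrated interval mapping to
    ``rate_range`` Hz, starts from a randomized phase, and drives its own
    output gate through gspike(v) = 1/(1+exp(-v/2)); the population gate
    is the mean over neurons (hence in [0, 1]).

    Returns (t, s_pop, spike_counts).
    """
    if n_neurons < 1:
        raise ValueError("n_neurons must be >= 1")
    base = base or default_gaba_params()
    rng = np.random.default_rng(seed)
    lo = _iapp_for_rate(rate_range[0])
    hi = _iapp_for_rate(rate_range[1])
    i_apps = rng.uniform(lo, hi, n_neurons)
    G = np.stack([_kernels.pack_gaba_params(base.replace(i_app=i))
                  for i in i_apps])
    y0 = np.empty((n_neurons, 4))
    y0[:, 0] = rng.uniform(-70.0, -50.0, n_neurons)   # random phases
    y0[:, 1] = 0.8
    y0[:, 2] = 0.1
    y0[:, 3] = 0.0
    n_steps = int(round(duration / dt))
    rec_stride = max(1, int(round(record_dt / dt)))
    s_pop, _, counts = _kernels.integrate_gaba_population(
        G, y0, dt, n_steps, TAU_GABA[0], TAU_GABA[1], rec_stride)
    t = np.arange(s_pop.size) * dt * rec_stride
    return t, s_pop, counts


def _iapp_for_rate(rate_hz: float) -> float:
    """Linear interpolation of the calibrated WB current-rate anchors."""
    f = (rate_hz - 12.0) / 10.0
    return GABA_IAPP_12HZ + f * (GABA_IAPP_22HZ - GABA_IAPP_12HZ)


# ---------------------------------------------------------------------------
# Ornstein-Uhlenbeck NMDA drive
# ---------------------------------------------------------------------------

def ou_trace(spec: OUSpec, duration: float, dt: float = 0.5,
             n_targets: int = 1, clip: bool = True):
    """Correlated OU conductance traces for ``n_targets`` neurons.

    Each trace is g_i(t) = mu + sigma*(sqrt(1-c)*x_i + sqrt(c)*x_c) with
    unit-variance OU processes x (exact discretization, stationary start),
    so that the stationary sd of g is sigma and the pairwise correlation
    between targets is c.  Negative excursions are clipped at zero before
    use as a conductance.

    Returns (t, g) with g of shape (n_steps+1, n_targets).
    """
    if dt > spec.tau / 2:
        raise ValueError("dt must be well below the OU correlation time")
    rng = np.random.default_rng(spec.seed)
    n_steps = int(round(duration / dt))
    rho = np.exp(-dt / spec.tau)
    noise = np.sqrt(1.0 - rho * rho)
    normals = rng.standard_normal((n_steps, n_targets + 1))
    x0 = rng.standard_normal(n_targets + 1)
    x = _kernels.ou_recursion(normals, rho, noise, x0)
    common = x[:, -1:]
    indep = x[:, :-1]
    g = spec.mu + spec.sigma * (np.sqrt(1.0 - spec.c) * indep
                                + np.sqrt(spec.c) * common)
    if clip:
        np.clip(g, 0.0, None, out=g)
    t = np.arange(n_steps + 1) * dt
    return t, g


def sine_modulated_ou(spec: OUSpec, mod_freq: float, mod_depth: float,
                      duration: float, dt: float = 0.5, n_targets: int = 1):
    """OU drive whose mean is multiplicatively modulated by a sine wave.

    g_i(t) = mu*(1 + mod_depth*sin(2*pi*f*t)) + fluctuations; with
    mod_depth = 0 this reproduces :func:`ou_trace` exactly (same seed).
    """
    if mod_freq <= 0:
        raise ValueError("mod_freq must be > 0")
    t, g = ou_trace(spec, duration, dt, n_targets, clip=False)
    envelope = spec.mu * mod_depth * np.sin(2e-3 * np.pi * mod_freq * t)
    g = g + envelope[:, None]
    np.clip(g, 0.0, None, out=g)
    return t, g
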
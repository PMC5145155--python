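"""Integration of the DA-neuron model under arbitrary drive, spike
detection, firing statistics, F-I curves, and conductance-plane sweeps.

Numerics: fixed-step RK4 (numba kernel), default step 0.02 ms for the full
model and 0.05 ms for the reduced (no spike currents) variants; halving the
step changes spike counts over 10 s by at most one (checked in the test
suite).  Spikes are upward threshold crossings (0 mV full model, -40 mV
reduced) with a 2 ms refractory guard against double counts on dense grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _kernels
from .params import DAParams, ModelVariant

__all__ = [
    "SimulationResult", "FICurve", "HeatMap",
    "integrate", "detect_spikes", "firing_stats",
    "conductance_plane_sweep", "balance_line", "fi_curve",
    "depolarization_block_detect", "steady_state_rate",
]

DEFAULT_TRANSIENT = 2000.0   # ms discarded before analysing any trace
DEFAULT_DURATION = 10000.0   # ms of analysed activity per sweep point
REFRACTORY = 2.0             # ms guard between detected spikes
BLOCK_MEAN_V = -55.0         # mV; depolarization-block mean-voltage cutoff
BLOCK_PTP = 5.0              # mV; depolarization-block amplitude cutoff

_REST_STATE = np.array([-60.0, 0.2, 0.01, 0.6, 0.05])


@dataclass
class SimulationResult:
    """A voltage/calcium trajectory with detected spikes and metadata."""

    time: np.ndarray          # ms
    v: np.ndarray             # mV
    ca: np.ndarray            # uM
    q: np.ndarray
    h: np.ndarray
    n: np.ndarray
    spike_times: np.ndarray   # ms
    transient: float          # ms, discarded before statistics
    variant: ModelVariant
    diverged: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def post_transient_spikes(self) -> np.ndarray:
        return self.spike_times[self.spike_times >= self.transient]

    def post_transient(self, arr: np.ndarray) -> np.ndarray:
        return arr[self.time >= self.transient]

    @property
    def final_state(self) -> np.ndarray:
        return np.array([self.v[-1], self.ca[-1], self.q[-1],
                         self.h[-1], self.n[-1]])


@dataclass
class FICurve:
    """Steady-state rate versus a swept parameter, with sweep direction."""

    param: str
    values: np.ndarray
    rates: np.ndarray         # Hz
    direction: str = "rising"

    def __post_init__(self) -> None:
        if np.any(self.rates[np.isfinite(self.rates)] < 0):
            raise ValueError("rates must be >= 0")


@dataclass
class HeatMap:
    """Rate / CV / depolarization-block maps over a 2-parameter plane."""

    x_param: str
    y_param: str
    x_grid: np.ndarray
    y_grid: np.ndarray
    rate: np.ndarray          # (ny, nx) Hz
    cv: np.ndarray            # (ny, nx)
    block: np.ndarray         # (ny, nx) bool
    failed: np.ndarray        # (ny, nx) bool: solver failure

    def __post_init__(self) -> None:
        shape = (len(self.y_grid), len(self.x_grid))
        for name in ("rate", "cv", "block", "failed"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} must have shape {shape}")


def _as_input(x, n_steps: int) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if arr.size not in (1,) and arr.size < 1:
        raise ValueError("empty input array")
    return arr


def default_dt(variant: ModelVariant) -> float:
    return 0.02 if variant.include_spike_currents else 0.05


_DRIVE_KEYS = {"g_nmda", "g_ampa", "g_gaba", "i_app", "input_dt",
               "g_eff", "e_eff"}


def _split_drive(drive: dict, params: DAParams) -> dict:
    """Normalize a drive dict; (g_eff, e_eff) becomes an AMPA/GABA mix.

    A combined ohmic synapse with reversal e_eff in [E_gaba, 0] is realized
    exactly by g_gaba = g_eff*e_eff/E_gaba and g_ampa = g_eff - g_gaba.
    """
    unknown = set(drive) - _DRIVE_KEYS
    if unknown:
        raise ValueError(f"unknown drive parameters: {sorted(unknown)}")
    drive = dict(drive)
    g_eff = drive.pop("g_eff", None)
    e_eff = drive.pop("e_eff", params.E_gaba)
    if g_eff is not None:
        if not params.E_gaba <= e_eff <= 0.0:
            raise ValueError("e_eff must lie between E_gaba and 0")
        g_gaba = g_eff * e_eff / params.E_gaba
        drive["g_gaba"] = drive.get("g_gaba", 0.0) + g_gaba
        drive["g_ampa"] = drive.get("g_ampa", 0.0) + (g_eff - g_gaba)
    return drive


def integrate(params: DAParams, variant: ModelVariant, duration: float,
              *, dt: float | None = None, g_nmda=0.0, g_ampa=0.0, g_gaba=0.0,
              i_app=0.0, g_eff=None, e_eff=None,
              y0: np.ndarray | None = None,
              input_dt: float | None = None, record_dt: float = 0.1,
              transient: float = DEFAULT_TRANSIENT) -> SimulationResult:
    """Integrate the model for ``duration`` ms (including the transient).

    Drive arguments may be scalars (tonic drive) or arrays sampled every
    ``input_dt`` ms (held piecewise-constant).  Synaptic conductances are
    effective values: maximal conductance times receptor gating.
    Divergence (non-finite state) truncates the trajectory and sets
    ``result.diverged``.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if g_eff is not None:
        mix = _split_drive({"g_eff": g_eff, "e_eff": e_eff
                            if e_eff is not None else params.E_gaba}, params)
        g_gaba = g_gaba + mix.get("g_gaba", 0.0)
        g_ampa = g_ampa + mix.get("g_ampa", 0.0)
    if dt is None:
        dt = default_dt(variant)
    n_steps = int(round(duration / dt))
    input_stride = 1 if input_dt is None else max(1, int(round(input_dt / dt)))
    rec_stride = max(1, int(round(record_dt / dt)))
    y0 = _REST_STATE.copy() if y0 is None else np.asarray(y0, dtype=float)
    P = _kernels.pack_da_params(params)
    F = _kernels.pack_variant(variant)
    rec, n_valid = _kernels.integrate_da(
        P, F, y0, dt, n_steps,
        _as_input(g_nmda, n_steps), _as_input(g_ampa, n_steps),
        _as_input(g_gaba, n_steps), _as_input(i_app, n_steps),
        input_stride, rec_stride)
    diverged = n_valid < rec.shape[0]
    rec = rec[:n_valid]
    time = np.arange(n_valid) * (dt * rec_stride)
    spikes = detect_spikes(time, rec[:, 0], variant)
    return SimulationResult(time=time, v=rec[:, 0], ca=rec[:, 1], q=rec[:, 2],
                            h=rec[:, 3], n=rec[:, 4], spike_times=spikes,
                            transient=min(transient, duration), variant=variant,
                            diverged=diverged,
                            meta={"dt": dt, "record_dt": dt * rec_stride})


def detect_spikes(time: np.ndarray, v: np.ndarray,
                  variant: ModelVariant | float,
                  refractory: float = REFRACTORY) -> np.ndarray:
    """Upward threshold crossings of v(t) with a refractory guard.

    The threshold is taken from the model variant (0 mV with spike currents,
    -40 mV without); a bare float may be passed instead.  Subthreshold
    oscillations never reach the threshold and are not counted.
    """
    thr = variant if isinstance(variant, (int, float)) else variant.spike_threshold
    v = np.asarray(v, dtype=float)
    up = np.flatnonzero((v[:-1] < thr) & (v[1:] >= thr))
    if up.size == 0:
        return np.empty(0)
    t_cross = np.asarray(time)[up + 1]
    keep = [0]
    for i in range(1, t_cross.size):
        if t_cross[i] - t_cross[keep[-1]] >= refractory:
            keep.append(i)
    return t_cross[keep]


def firing_stats(spikes: Sequence[float], n_isis: int = 200,
                 min_isis: int | None = None) -> tuple[float, float]:
    """(rate [Hz], ISI CV) from spike times in ms.

    Rate is the inverse mean interspike interval (needs >= 2 spikes, else
    NaN).  CV is sd/mean over the last ``n_isis`` ISIs; with fewer than
    ``min_isis`` (default: ``n_isis``) available it is NaN.
    """
    spikes = np.asarray(spikes, dtype=float)
    if spikes.size < 2:
        return (np.nan, np.nan)
    isis = np.diff(spikes)
    rate = 1000.0 / isis.mean()
    min_isis = n_isis if min_isis is None else min_isis
    if isis.size < min_isis:
        return (rate, np.nan)
    tail = isis[-n_isis:]
    return (rate, float(tail.std() / tail.mean()))


def steady_state_rate(params: DAParams, variant: ModelVariant, *,
                      duration: float = DEFAULT_DURATION,
                      transient: float = DEFAULT_TRANSIENT,
                      dt: float | None = None,
                      y0: np.ndarray | None = None,
                      return_state: bool = False,
                      **drive) -> float | tuple[float, np.ndarray, int]:
    """Steady-state firing rate under tonic drive (fast spike-only path)."""
    if dt is None:
        dt = default_dt(variant)
    n_steps = int(round((duration + transient) / dt))
    y0 = _REST_STATE.copy() if y0 is None else np.asarray(y0, dtype=float)
    P = _kernels.pack_da_params(params)
    F = _kernels.pack_variant(variant)
    drive = _split_drive(drive, params)
    g_nmda = drive.get("g_nmda", 0.0)
    g_ampa = drive.get("g_ampa", 0.0)
    g_gaba = drive.get("g_gaba", 0.0)
    i_app = drive.get("i_app", 0.0)
    input_dt = drive.get("input_dt")
    stride = 1 if input_dt is None else max(1, int(round(input_dt / dt)))
    times, count, y_final, ok = _kernels.da_spike_times(
        P, F, y0, dt, n_steps,
        _as_input(g_nmda, n_steps), _as_input(g_ampa, n_steps),
        _as_input(g_gaba, n_steps), _as_input(i_app, n_steps),
        stride, float(variant.spike_threshold), REFRACTORY, 200000)
    post = times[times >= transient]
    rate, _ = firing_stats(post, min_isis=1)
    rate = 0.0 if not np.isfinite(rate) else rate
    if post.size == 1:
        rate = 1000.0 / (duration)  # single spike: bounded estimate
    if return_state:
        return rate, y_final, ok
    return rate


def depolarization_block_detect(result: SimulationResult,
                                mean_v_cutoff: float = BLOCK_MEAN_V,
                                ptp_cutoff: float = BLOCK_PTP) -> bool:
    """True iff the post-transient segment shows depolarization block.

    Block = no spikes AND mean voltage above ``mean_v_cutoff`` AND
    peak-to-peak voltage below ``ptp_cutoff`` (a depolarized, nearly flat
    membrane).  A hyperpolarized rest state is quiescence, not block.
    """
    v = result.post_transient(result.v)
    if v.size == 0:
        raise ValueError("no post-transient segment available")
    if result.post_transient_spikes.size > 0:
        return False
    return bool(v.mean() > mean_v_cutoff and np.ptp(v) < ptp_cutoff)


def conductance_plane_sweep(params: DAParams, variant: ModelVariant,
                            x: tuple[str, np.ndarray],
                            y: tuple[str, np.ndarray], *,
                            duration: float = DEFAULT_DURATION,
                            transient: float = DEFAULT_TRANSIENT,
                            dt: float | None = None,
                            cv_min_isis: int = 10,
                            extra_drive: dict | None = None) -> HeatMap:
    """Steady-state rate/CV/block maps over a tonic-conductance plane.

    ``x`` and ``y`` name any of the tonic drive parameters
    (g_nmda/g_ampa/g_gaba/i_app) with their grids.  Per-cell solver
    failures are recorded in ``failed`` and the sweep continues.
    """
    x_name, x_grid = x
    y_name, y_grid = y
    x_grid = np.asarray(x_grid, dtype=float)
    y_grid = np.asarray(y_grid, dtype=float)
    if x_grid.size == 0 or y_grid.size == 0:
        raise ValueError("grids must be nonempty")
    shape = (y_grid.size, x_grid.size)
    rate = np.zeros(shape)
    cv = np.full(shape, np.nan)
    block = np.zeros(shape, dtype=bool)
    failed = np.zeros(shape, dtype=bool)
    if dt is None:
        dt = default_dt(variant)
    for iy, yv in enumerate(y_grid):
        for ix, xv in enumerate(x_grid):
            drive = dict(extra_drive or {})
            drive[x_name] = xv
            drive[y_name] = yv
            res = integrate(params, variant, duration + transient, dt=dt,
                            transient=transient, record_dt=0.2, **drive)
            if res.diverged:
                failed[iy, ix] = True
                continue
            r, c = firing_stats(res.post_transient_spikes, min_isis=cv_min_isis)
            rate[iy, ix] = 0.0 if not np.isfinite(r) else r
            cv[iy, ix] = c
            block[iy, ix] = depolarization_block_detect(res)
    return HeatMap(x_param=x_name, y_param=y_name, x_grid=x_grid,
                   y_grid=y_grid, rate=rate, cv=cv, block=block, failed=failed)


def balance_line(hmap: HeatMap, rate_band: tuple[float, float]
                 ) -> tuple[float, float, float]:
    """Least-squares line g_NMDA = slope * g_GABA + b through band cells.

    Cells whose steady-state rate lies inside ``rate_band`` define the
    balanced region; the fitted slope is the NMDA/GABA trade-off ratio.
    Requires the map's x-parameter to be g_gaba and y to be g_nmda (or the
    transpose).
    """
    lo, hi = rate_band
    mask = (hmap.rate >= lo) & (hmap.rate <= hi) & ~hmap.failed
    if {hmap.x_param, hmap.y_param} != {"g_gaba", "g_nmda"}:
        raise ValueError("balance line requires a g_nmda/g_gaba plane")
    yy, xx = np.meshgrid(hmap.y_grid, hmap.x_grid, indexing="ij")
    if hmap.x_param == "g_gaba":
        g_gaba, g_nmda = xx[mask], yy[mask]
    else:
        g_gaba, g_nmda = yy[mask], xx[mask]
    if g_gaba.size < 3:
        raise ValueError("fewer than 3 cells fall in the rate band")
    coeffs, res, *_ = np.polyfit(g_gaba, g_nmda, 1, full=True)
    slope, intercept = float(coeffs[0]), float(coeffs[1])
    residual = float(res[0]) if len(res) else 0.0
    return slope, intercept, residual


def fi_curve(params: DAParams, variant: ModelVariant, param: str,
             grid: np.ndarray, *, direction: str = "rising",
             duration: float = DEFAULT_DURATION,
             transient: float = DEFAULT_TRANSIENT,
             carry_state: bool = True,
             extra_drive: dict | None = None,
             y0: np.ndarray | None = None) -> FICurve:
    """Steady-state rate along a parameter ramp (slow-ramp emulation).

    With ``carry_state`` the final state at each point seeds the next,
    emulating a slowly rising (or, for ``direction='falling'``, falling)
    ramp, which exposes hysteresis when spiking and resting states coexist.
    """
    grid = np.asarray(grid, dtype=float)
    diffs = np.diff(grid)
    if grid.size and not (np.all(diffs >= 0) or np.all(diffs <= 0)):
        raise ValueError("grid must be monotone")
    order = np.arange(grid.size)
    if direction == "falling":
        order = order[::-1]
    elif direction != "rising":
        raise ValueError("direction must be 'rising' or 'falling'")
    rates = np.zeros(grid.size)
    state = y0
    for idx in order:
        drive = dict(extra_drive or {})
        drive[param] = grid[idx]
        r, y_final, ok = steady_state_rate(
            params, variant, duration=duration, transient=transient,
            y0=state, return_state=True, **drive)
        rates[idx] = r if ok else np.nan
        if carry_state and ok:
            state = y_final
    return FICurve(param=param, values=grid, rates=rates, direction=direction)
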
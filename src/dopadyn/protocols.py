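"""Protocol configs: declarative YAML descriptions of every analysis run.

A protocol file selects a ``kind`` (trace, plane_sweep, fi_curve,
hysteresis, classify, bt_boundary, ih_cusp, population, reward), a model
variant, parameter overrides, drive and sweep settings, and a seed.
``run_protocol`` validates the config (unknown keys are rejected), executes
it, and writes tidy CSV tables plus a JSON metadata/verdict file and a log
into the output directory.
"""

from __future__ import annotations

import dataclasses
import json
import time
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dynamics_analysis as dyn
from . import simulation_engine as se
from .params import DAParams, ModelVariant, default_params
from .population_release import (PopulationSpec, etoh_protocol,
                                 reward_coding_protocol, simulate_population,
                                 synchrony_index)
from .synaptic_inputs import OUSpec

__all__ = ["run_protocol", "load_protocol", "make_fixtures", "packaged_protocol"]

_KINDS = ("trace", "plane_sweep", "fi_curve", "hysteresis", "classify",
          "bt_boundary", "ih_cusp", "population", "etoh", "reward",
          "nullclines")

_TOP_KEYS = {"kind", "name", "seed", "variant", "params", "drive", "sweep",
             "duration", "transient", "x", "y", "param", "grid", "direction",
             "e_grid", "rate_band", "population", "reward_values", "options"}

_VARIANTS = {
    "full": ModelVariant.full,
    "reduced": ModelVariant.reduced,
    "ca_k_only": ModelVariant.ca_k_only,
}


def packaged_protocol(name: str) -> Path:
    """Path of a protocol shipped with the package (e.g. 'fig2')."""
    ref = resources.files("dopadyn") / "protocol_configs" / f"{name}.yaml"
    return Path(str(ref))


def load_protocol(path: str | Path) -> dict:
    p = Path(path)
    if not p.exists():
        candidate = packaged_protocol(str(path))
        if candidate.exists():
            p = candidate
    cfg = yaml.safe_load(Path(p).read_text())
    if not isinstance(cfg, dict):
        raise ValueError("protocol must be a mapping")
    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown protocol keys: {sorted(unknown)}")
    if cfg.get("kind") not in _KINDS:
        raise ValueError(f"kind must be one of {_KINDS}")
    for key in ("params", "drive"):
        block = cfg.get(key, {})
        if not isinstance(block, dict):
            raise ValueError(f"{key} must be a mapping")
        for k, v in block.items():
            if isinstance(v, (int, float)) and k.startswith(("g", "gbar")) and v < 0:
                raise ValueError(f"{key}.{k}: conductance must be >= 0")
    return cfg


def _build(cfg: dict) -> tuple[DAParams, ModelVariant]:
    params = default_params()
    overrides = cfg.get("params", {})
    params = params.replace(**overrides)
    vname = cfg.get("variant", "full")
    if vname not in _VARIANTS:
        raise ValueError(f"unknown variant: {vname}")
    variant = _VARIANTS[vname]()
    if params.g_h > 0:
        variant.include_ih = True
    return params, variant


def _grid(spec) -> np.ndarray:
    if isinstance(spec, dict):
        return np.linspace(spec["start"], spec["stop"], int(spec["num"]))
    return np.asarray(spec, dtype=float)


def run_protocol(config: str | Path | dict, out_dir: str | Path = "results",
                 seed: int | None = None) -> dict:
    """Execute a protocol config and write its result bundle to disk.

    Returns the metadata dict (also written as ``<name>_meta.json``).
    """
    cfg = load_protocol(config) if not isinstance(config, dict) else config
    name = cfg.get("name", cfg["kind"])
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0)) if seed is None else int(seed)
    params, variant = _build(cfg)
    duration = float(cfg.get("duration", 10000.0))
    transient = float(cfg.get("transient", 2000.0))
    drive = dict(cfg.get("drive", {}))
    opts = dict(cfg.get("options", {}))
    t0 = time.time()
    meta: dict = {"name": name, "kind": cfg["kind"], "seed": seed,
                  "params": dataclasses.asdict(params)}
    tables: dict[str, pd.DataFrame] = {}

    if cfg["kind"] == "trace":
        if opts.get("asynchronous"):
            drive = _asynchronous_drive(params, duration, seed, drive)
        res = se.integrate(params, variant, duration, transient=transient,
                           **drive)
        tables["trace"] = pd.DataFrame({
            "time_ms": res.time, "v_mV": res.v, "ca_uM": res.ca})
        tables["spikes"] = pd.DataFrame({"time_ms": res.spike_times})
        rate, cv = se.firing_stats(res.post_transient_spikes, min_isis=2)
        meta["rate_hz"] = rate
        meta["block"] = se.depolarization_block_detect(res)

    elif cfg["kind"] == "plane_sweep":
        x = (cfg["x"]["param"], _grid(cfg["x"]))
        y = (cfg["y"]["param"], _grid(cfg["y"]))
        hmap = se.conductance_plane_sweep(params, variant, x, y,
                                          duration=duration,
                                          transient=transient,
                                          extra_drive=drive)
        yy, xx = np.meshgrid(hmap.y_grid, hmap.x_grid, indexing="ij")
        tables["heatmap"] = pd.DataFrame({
            hmap.x_param: xx.ravel(), hmap.y_param: yy.ravel(),
            "rate_hz": hmap.rate.ravel(), "cv": hmap.cv.ravel(),
            "block": hmap.block.ravel(), "failed": hmap.failed.ravel()})
        if "rate_band" in cfg:
            slope, intercept, resid = se.balance_line(hmap, tuple(cfg["rate_band"]))
            meta["balance"] = {"slope": slope, "intercept": intercept,
                               "residual": resid}

    elif cfg["kind"] in ("fi_curve", "hysteresis"):
        grid = _grid(cfg["grid"])
        directions = (["rising", "falling"] if cfg["kind"] == "hysteresis"
                      else [cfg.get("direction", "rising")])
        frames = []
        for d in directions:
            fi = se.fi_curve(params, variant, cfg["param"], grid,
                             direction=d, duration=duration,
                             transient=transient, extra_drive=drive)
            frames.append(pd.DataFrame({
                "param": fi.param, "value": fi.values, "rate_hz": fi.rates,
                "direction": d}))
            verdict = dyn.excitability_type(fi)
            meta[f"excitability_{d}"] = dataclasses.asdict(verdict)
        tables["fi_curve"] = pd.concat(frames, ignore_index=True)

    elif cfg["kind"] == "classify":
        bp = dyn.classify_transition(params, variant, cfg["param"],
                                     _grid(cfg["grid"]), extra_drive=drive,
                                     duration=duration, transient=transient)
        meta["bifurcation"] = {"kind": bp.kind, "param": bp.param,
                               "value": bp.value,
                               "onset_rate_hz": bp.onset_rate_hz,
                               "diagnostics": bp.diagnostics}

    elif cfg["kind"] == "bt_boundary":
        e_lo, e_hi = cfg.get("e_grid", [-90.0, -60.0])
        meta["bt_e_eff_mV"] = dyn.bt_boundary(
            params, g_nmda=drive.get("g_nmda", 0.0), e_grid=(e_lo, e_hi),
            **opts)
        try:
            e_alg, g_alg, v_alg = dyn.bt_point(params,
                                               g_nmda=drive.get("g_nmda", 0.0))
            meta["bt_algebraic"] = {"e_eff_mV": e_alg, "g_eff": g_alg,
                                    "v_mV": v_alg}
        except RuntimeError:
            meta["bt_algebraic"] = None

    elif cfg["kind"] == "ih_cusp":
        meta["gh_critical"] = dyn.ih_fold_critical_gh(params, **opts)

    elif cfg["kind"] == "population":
        pop = dict(cfg.get("population", {}))
        ou = OUSpec(**pop.pop("ou", {}), seed=seed)
        spec = PopulationSpec(params=params, ou=ou, seed=seed, **pop)
        res = simulate_population(spec, duration, **opts)
        rows = [(i, t) for i, spk in enumerate(res.raster) for t in spk]
        tables["raster"] = pd.DataFrame(rows, columns=["neuron_id", "time_ms"])
        tables["da"] = pd.DataFrame({"time_ms": res.da.t, "da_uM": res.da.da,
                                     "cumulative_uM": res.da.cumulative})
        meta["mean_rate_hz"] = res.mean_rate
        meta["synchrony"] = synchrony_index(res.raster, duration=duration,
                                            seed=seed)
        meta["cumulative_da_uM"] = float(res.da.cumulative[-1])

    elif cfg["kind"] == "etoh":
        pop = dict(cfg.get("population", {}))
        ou = OUSpec(**pop.pop("ou", {}), seed=seed)
        spec = PopulationSpec(params=params, ou=ou, seed=seed, **pop)
        out_e = etoh_protocol(spec, **opts)
        for cond in ("control", "etoh"):
            r = out_e[cond]["result"]
            tables[f"da_{cond}"] = pd.DataFrame({
                "time_ms": r.da.t, "da_uM": r.da.da,
                "cumulative_uM": r.da.cumulative})
            meta[cond] = {k: out_e[cond][k]
                          for k in ("synchrony", "cumulative_da", "mean_rate")}

    elif cfg["kind"] == "nullclines":
        nc = dyn.nullclines(params, **{k: v for k, v in opts.items()},
                            **{k: v for k, v in drive.items()
                               if k in ("g_nmda", "g_eff", "e_eff", "i_app")})
        tables["ca_nullcline"] = pd.DataFrame({
            "v_mV": nc.v, "ca_uM": nc.ca_nullcline})
        tables["v_nullcline"] = pd.DataFrame({
            "v_mV": nc.v_nullcline_v, "ca_uM": nc.v_nullcline_ca})

    elif cfg["kind"] == "reward":
        out_r = reward_coding_protocol(params, cfg["reward_values"], **opts)
        tables["reward"] = pd.DataFrame({
            "reward_value": out_r["reward_values"],
            "rate_hz": out_r["second_pulse_rate"]})
        meta["type"] = out_r["type"]

    meta["runtime_s"] = round(time.time() - t0, 3)
    for tname, df in tables.items():
        df.to_csv(out / f"{name}_{tname}.csv", index=False)
    (out / f"{name}_meta.json").write_text(json.dumps(meta, indent=2,
                                                      default=_jsonify))
    (out / f"{name}.log").write_text(
        f"{name}: kind={cfg['kind']} seed={seed} "
        f"runtime={meta['runtime_s']}s tables={sorted(tables)}\n")
    return meta


def _asynchronous_drive(params, duration, seed, drive):
    """Replace tonic NMDA/GABA values by asynchronous gating traces.

    Glutamate: 35 Poisson trains at ~10 Hz with an NMDA coincidence
    threshold driving the NMDA gate; GABA: the averaged gate of a 30-neuron
    Wang-Buzsaki population.  The tonic g_nmda/g_gaba entries are taken as
    maximal conductances and multiplied by the gating traces.
    """
    from .synaptic_inputs import (ReceptorGating, coincidence_drive,
                                  gaba_population_drive, gating_trace,
                                  poisson_glu_trains)
    input_dt = 0.1
    out = dict(drive)
    g_nmda = out.pop("g_nmda", 0.0)
    g_gaba = out.pop("g_gaba", 0.0)
    if g_nmda:
        trains = poisson_glu_trains(35, 10.0, duration, seed)
        j = coincidence_drive(trains, dt=input_dt)
        s = gating_trace(j, input_dt, ReceptorGating.nmda())
        out["g_nmda"] = g_nmda * s[:-1]
    if g_gaba:
        _, s_pop, _ = gaba_population_drive(30, duration, seed=seed + 1,
                                            record_dt=input_dt)
        out["g_gaba"] = g_gaba * s_pop[:len(np.arange(0, duration, input_dt))]
    out["input_dt"] = input_dt
    return out


def _jsonify(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def make_fixtures(seed: int = 0, out_dir: str | Path = "fixtures") -> dict:
    """Small canned inputs for unit tests, regenerated deterministically.

    Produces a 1 s Poisson spike-train set, a 1 s OU conductance trace,
    and samples of the theta-model normal form dtheta/dt = I - cos(theta)
    (SNIC at I = 1), written as CSVs.
    """
    from .synaptic_inputs import poisson_glu_trains, ou_trace
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trains = poisson_glu_trains(n=35, rate=10.0, duration=1000.0, seed=seed)
    rows = [(i, t) for i, spk in enumerate(trains.trains) for t in spk]
    pd.DataFrame(rows, columns=["train_id", "time_ms"]).to_csv(
        out / "poisson_trains.csv", index=False)
    t, g = ou_trace(OUSpec(seed=seed), duration=1000.0, dt=0.5)
    pd.DataFrame({"time_ms": t, "g_mS_cm2": g[:, 0]}).to_csv(
        out / "ou_trace.csv", index=False)
    i_vals = np.linspace(0.8, 1.5, 15)
    rates = [theta_model_rate(i) for i in i_vals]
    pd.DataFrame({"i": i_vals, "rate_hz": rates}).to_csv(
        out / "theta_model.csv", index=False)
    return {"poisson_trains": trains, "ou": (t, g), "theta": (i_vals, rates)}


def theta_model_rate(i: float) -> float:
    """Firing rate (Hz) of dtheta/dt = i - cos(theta) per ms.

    Closed form sqrt(i^2-1)/(2*pi) kHz above the SNIC at i = 1; 0 below.
    """
    if i <= 1.0:
        return 0.0
    return float(np.sqrt(i * i - 1.0) / (2.0 * np.pi) * 1000.0)
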
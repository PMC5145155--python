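"""Parameter and state containers for the dopamine (DA) neuron model.

All quantities use a single unit convention: voltages in mV, time in ms,
conductances in mS/cm^2, capacitance in uF/cm^2, calcium concentration in uM,
currents in uA/cm^2.  With the compartment radius ``r`` expressed in cm and
Faraday's constant in C/mol, the calcium balance

    d[Ca]/dt = (2*beta/r) * ( (g_Ca(v) + f_leak*g_l) * (E_Ca - v) / (z*F)
                              - P_Ca * [Ca] )

comes out in uM/ms with no extra conversion factor, so the pump rate ``P_Ca``
carries units of cm/ms.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "DAParams",
    "DAState",
    "GABAParams",
    "GABAState",
    "ModelVariant",
    "load_params",
    "save_params",
    "default_params",
    "default_gaba_params",
]

FARADAY = 96485.0  # C/mol


@dataclass
class DAParams:
    """Biophysical parameters of the one-compartment DA neuron.

    Maximal conductances and reversal potentials follow the shipped
    ``table1.yaml``; the calcium-handling block (``beta_ca``, ``r``, ``P_Ca``,
    ``K_sk``) and the L-type activation curve (``ca_vhalf``, ``ca_k``) are
    calibration constants of this package (see docs/methods.md).
    """

    c_m: float = 1.0          # uF/cm^2
    gbar_Ca: float = 2.5      # mS/cm^2
    gbar_KCa: float = 7.8
    gbar_K: float = 1.0
    gbar_sNa: float = 0.13
    gbar_Na: float = 50.0
    gbar_DR: float = 2.0
    g_l: float = 0.18
    g_h: float = 0.0          # Ih off by default; swept in the Ih analyses
    E_Ca: float = 50.0        # mV
    E_K: float = -90.0
    E_Na: float = 55.0
    E_l: float = -35.0
    E_h: float = -25.0
    E_gaba: float = -90.0
    # Calcium handling
    beta_ca: float = 0.045    # free-to-total Ca ratio
    r: float = 2.0e-4         # compartment radius, cm (2 um)
    z: float = 2.0            # Ca valence
    F: float = FARADAY
    P_Ca: float = 2.56e-6     # pump removal rate, cm/ms (calibrated)
    K_sk: float = 78.0        # SK half-activation [Ca], uM (calibrated)
    ca_leak_frac: float = 0.1  # fraction of leak conductance carrying Ca
    # L-type Ca activation (instantaneous Boltzmann; calibrated)
    ca_vhalf: float = -42.0   # mV
    ca_k: float = 6.0         # mV, slope
    # NMDA voltage dependence (Jahr-Stevens Mg block)
    Mg: float = 0.5           # mM
    m_e: float = 0.062        # 1/mV

    def __post_init__(self) -> None:
        for name in ("gbar_Ca", "gbar_KCa", "gbar_K", "gbar_sNa", "gbar_Na",
                     "gbar_DR", "g_l", "g_h"):
            if getattr(self, name) < 0:
                raise ValueError(f"conductance {name} must be >= 0")
        if self.c_m <= 0:
            raise ValueError("c_m must be > 0")
        if not (self.E_K < self.E_l < self.E_Na):
            raise ValueError("require E_K < E_l < E_Na")
        if self.K_sk <= 0:
            raise ValueError("K_sk must be > 0")
        if not 0.0 <= self.ca_leak_frac <= 1.0:
            raise ValueError("ca_leak_frac must lie in [0, 1]")

    @property
    def ca_flux_coeff(self) -> float:
        """2*beta/(r*z*F): converts uA/cm^2 of Ca current into uM/ms."""
        return 2.0 * self.beta_ca / (self.r * self.z * self.F)

    @property
    def ca_pump_rate(self) -> float:
        """(2*beta/r)*P_Ca: linear Ca removal rate, 1/ms."""
        return 2.0 * self.beta_ca / self.r * self.P_Ca

    def replace(self, **kw) -> "DAParams":
        return dataclasses.replace(self, **kw)


@dataclass
class DAState:
    """Dynamic variables of the DA neuron: voltage, calcium, and gates."""

    v: float = -60.0   # mV
    ca: float = 0.1    # uM
    q: float = 0.0     # Ih activation
    h: float = 0.6     # fast-Na inactivation
    n: float = 0.1     # delayed-rectifier activation

    def __post_init__(self) -> None:
        if self.ca < 0:
            raise ValueError("ca must be >= 0")
        for g in ("q", "h", "n"):
            if not 0.0 <= getattr(self, g) <= 1.0:
                raise ValueError(f"gate {g} must lie in [0, 1]")

    def as_array(self):
        import numpy as np
        return np.array([self.v, self.ca, self.q, self.h, self.n])


@dataclass
class ModelVariant:
    """Switches selecting the full or reduced vector field.

    The reduced model removes the spike-producing fast Na and delayed
    rectifier currents and registers spikes at -40 mV instead of 0 mV.
    """

    include_spike_currents: bool = True
    include_sNa: bool = True
    include_ih: bool = False
    include_ca_leak: bool = True
    spike_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.spike_threshold is None:
            self.spike_threshold = 0.0 if self.include_spike_currents else -40.0

    @classmethod
    def full(cls, **kw) -> "ModelVariant":
        return cls(include_spike_currents=True, **kw)

    @classmethod
    def reduced(cls, **kw) -> "ModelVariant":
        """No spike currents; subthreshold Na retained."""
        return cls(include_spike_currents=False, **kw)

    @classmethod
    def ca_k_only(cls, **kw) -> "ModelVariant":
        """Pure Ca(2+)-K(+) oscillator: spike currents and sNa removed."""
        return cls(include_spike_currents=False, include_sNa=False, **kw)


@dataclass
class GABAParams:
    """Wang-Buzsaki fast-spiking interneuron parameters."""

    c_m: float = 1.0
    gbar_Nag: float = 22.0
    gbar_Kg: float = 7.0
    g_lg: float = 0.1
    E_Na: float = 55.0
    E_K: float = -90.0
    E_lg: float = -51.0
    i_app: float = 0.0

    def __post_init__(self) -> None:
        for name in ("gbar_Nag", "gbar_Kg", "g_lg"):
            if getattr(self, name) < 0:
                raise ValueError(f"conductance {name} must be >= 0")

    def replace(self, **kw) -> "GABAParams":
        return dataclasses.replace(self, **kw)


@dataclass
class GABAState:
    v: float = -64.0
    h: float = 0.78
    n: float = 0.09

    def __post_init__(self) -> None:
        for g in ("h", "n"):
            if not 0.0 <= getattr(self, g) <= 1.0:
                raise ValueError(f"gate {g} must lie in [0, 1]")


_FIELDS = {f.name for f in dataclasses.fields(DAParams)}
_GFIELDS = {f.name for f in dataclasses.fields(GABAParams)}


def load_params(path: str | Path | None = None) -> DAParams:
    """Load DA-neuron parameters from a flat YAML mapping.

    With no argument, loads the packaged ``table1.yaml`` (printed parameter
    table plus the calibrated calcium-handling constants).  Unknown keys are
    rejected; keys under ``gaba`` are ignored here (see
    :func:`default_gaba_params`).
    """
    raw = _read_config(path)
    da = {k: v for k, v in raw.items() if k != "gaba"}
    unknown = set(da) - _FIELDS
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    return DAParams(**da)


def default_gaba_params(path: str | Path | None = None) -> GABAParams:
    raw = _read_config(path).get("gaba", {})
    unknown = set(raw) - _GFIELDS
    if unknown:
        raise ValueError(f"unknown GABA parameter keys: {sorted(unknown)}")
    return GABAParams(**raw)


def _read_config(path: str | Path | None) -> dict:
    if path is None:
        ref = resources.files("dopadyn") / "config" / "table1.yaml"
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError("parameter file must be a flat mapping")
    return raw


def default_params() -> DAParams:
    return load_params(None)


def save_params(p: DAParams, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(p), sort_keys=False))
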
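"""Vector fields and current formulas of the DA and GABA neuron models.

The DA neuron is a single-compartment conductance-based model whose
pacemaking core is the interplay of an instantaneously gated L-type Ca(2+)
current and an SK-type Ca(2+)-dependent K(+) current, augmented by a
voltage-gated K(+) current, a subthreshold (persistent) Na(+) current, the
hyperpolarization-activated cation current Ih, spike-producing fast Na(+)
and delayed-rectifier K(+) currents, an ohmic leak (with a small Ca(2+)
component), and NMDA/AMPA/GABA synaptic currents.  The GABA interneurons
driving the inhibitory input follow the Wang-Buzsaki fast-spiking model.

All functions accept scalars or numpy arrays for the voltage argument.
Rate functions with removable singularities (x/(1-exp(-x/k)) forms) are
evaluated by their analytic limit in a small neighbourhood of the singular
point.
"""

from __future__ import annotations

import numpy as np

from .params import DAParams, GABAParams, ModelVariant

__all__ = [
    "ca_conductance", "sk_conductance", "k_conductance", "sna_conductance",
    "ih_kinetics", "fast_na_rates", "dr_rates", "nmda_conductance",
    "da_rhs", "gaba_wb_rhs", "wb_rates", "effective_ohmic",
]

_SING_EPS = 1e-7


def _xexprel(x, k):
    """x / (1 - exp(-x/k)), with the analytic limit k at x = 0."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < _SING_EPS
    safe = np.where(small, 1.0, x)
    out = np.where(small, k + x / 2.0, safe / -np.expm1(-safe / k))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Intrinsic DA-neuron conductances and kinetics
# ---------------------------------------------------------------------------

def ca_conductance(v, params: DAParams):
    """Instantaneous L-type Ca(2+) conductance, mS/cm^2.

    A Boltzmann activation curve with half-activation ``ca_vhalf`` (near
    -50 mV, the low L-type threshold characteristic of DA cells) and slope
    ``ca_k``; both are calibration constants exposed in the config.
    """
    return params.gbar_Ca / (1.0 + np.exp(-(v - params.ca_vhalf) / params.ca_k))


def sk_conductance(ca, params: DAParams):
    """SK conductance as a Hill-4 function of [Ca], mS/cm^2."""
    ca = np.asarray(ca, dtype=float)
    if np.any(ca < 0):
        raise ValueError("calcium concentration must be >= 0")
    ca4 = ca ** 4
    out = params.gbar_KCa * ca4 / (ca4 + params.K_sk ** 4)
    return out if out.ndim else float(out)


def k_conductance(v, params: DAParams):
    """Voltage-gated K(+) conductance (Boltzmann, midpoint -10 mV)."""
    return params.gbar_K / (1.0 + np.exp(-(v + 10.0) / 7.0))


def sna_conductance(v, params: DAParams):
    """Subthreshold (persistent) Na(+) conductance, instantaneous."""
    return params.gbar_sNa / (1.0 + np.exp(-(v + 50.0) / 5.0))


def ih_kinetics(v):
    """Ih activation: (q_inf, tau_q[ms]).

    q_inf decreases with voltage (hyperpolarization-activated), midpoint
    -95 mV; tau_q peaks in the subthreshold range with tau_q(-112) = 312.5 ms.
    """
    v = np.asarray(v, dtype=float)
    q_inf = 1.0 / (1.0 + np.exp((v + 95.0) / 8.0))
    tau_q = 625.0 * np.exp(0.075 * (v + 112.0)) / (1.0 + np.exp(0.083 * (v + 112.0)))
    if q_inf.ndim:
        return q_inf, tau_q
    return float(q_inf), float(tau_q)


def fast_na_rates(v):
    """Fast Na(+): (m_inf, alpha_h, beta_h); activation is instantaneous."""
    v = np.asarray(v, dtype=float)
    alpha_m = 0.32 * _xexprel(v + 39.0, 4.0)
    beta_m = 0.28 * _xexprel(-(v + 4.0), 5.0)
    m_inf = alpha_m / (alpha_m + beta_m)
    alpha_h = 0.01 * np.exp(-(v + 47.0) / 18.0)
    beta_h = 1.25 / (1.0 + np.exp(-(v + 24.0) / 5.0))
    if v.ndim:
        return m_inf, alpha_h, beta_h
    return float(m_inf), float(alpha_h), float(beta_h)


def dr_rates(v):
    """Delayed-rectifier K(+) activation rates (alpha_n, beta_n)."""
    v = np.asarray(v, dtype=float)
    alpha_n = 0.0032 * _xexprel(v + 5.0, 10.0)
    beta_n = 0.05 * np.exp(-(v + 10.0) / 16.0)
    if v.ndim:
        return alpha_n, beta_n
    return float(alpha_n), float(beta_n)


def nmda_conductance(v, gbar_nmda, params: DAParams):
    """Mg-blocked NMDA conductance (Jahr-Stevens form).

    g(v) = gbar / (1 + ([Mg]/3.57)*exp(-m_e*v)) with [Mg] in mM and the
    shallow voltage-dependence slope m_e = 0.062/mV.  With the default
    [Mg] = 0.5 mM the block factor at -60 mV is ~0.15, which lets tonic
    GABA cancel tonic NMDA along the ~3.4:1 balance line (see
    docs/methods.md on this choice of prefactor).
    """
    if np.any(np.asarray(gbar_nmda) < 0):
        raise ValueError("gbar_nmda must be >= 0")
    out = gbar_nmda / (1.0 + params.Mg / 3.57
                       * np.exp(-params.m_e * np.asarray(v, dtype=float)))
    return out if np.ndim(out) else float(out)


# ---------------------------------------------------------------------------
# DA neuron vector field
# ---------------------------------------------------------------------------

def da_rhs(state, params: DAParams, variant: ModelVariant,
           g_nmda: float = 0.0, g_ampa: float = 0.0, g_gaba: float = 0.0,
           i_app: float = 0.0):
    """Time derivative of the DA-neuron state (v, ca, q, h, n).

    ``g_nmda``, ``g_ampa``, ``g_gaba`` are the *effective* synaptic
    conductances at this instant, i.e. maximal conductance times the receptor
    gating variable (tonic activation corresponds to gating = 1); the NMDA Mg
    block is applied internally.  Currents excluded by ``variant`` contribute
    exactly zero, and their gates are frozen.
    """
    v, ca, q, h, n = (float(x) for x in state)
    if not np.all(np.isfinite([v, ca, q, h, n])):
        raise FloatingPointError("non-finite state passed to da_rhs")

    i_total = i_app
    i_total += ca_conductance(v, params) * (params.E_Ca - v)
    i_total += (sk_conductance(ca, params) + k_conductance(v, params)) * (params.E_K - v)
    i_total += params.g_l * (params.E_l - v)
    if variant.include_sNa:
        i_total += sna_conductance(v, params) * (params.E_Na - v)
    if variant.include_ih:
        i_total += params.g_h * q * (params.E_h - v)
    if variant.include_spike_currents:
        m_inf, _, _ = fast_na_rates(v)
        i_total += params.gbar_Na * m_inf ** 3 * h * (params.E_Na - v)
        i_total += params.gbar_DR * n ** 4 * (params.E_K - v)
    i_total += nmda_conductance(v, g_nmda, params) * (0.0 - v)
    i_total += g_ampa * (0.0 - v)
    i_total += g_gaba * (params.E_gaba - v)

    dv = i_total / params.c_m

    g_ca_total = ca_conductance(v, params)
    if variant.include_ca_leak:
        g_ca_total += params.ca_leak_frac * params.g_l
    dca = (params.ca_flux_coeff * g_ca_total * (params.E_Ca - v)
           - params.ca_pump_rate * ca)

    if variant.include_ih:
        q_inf, tau_q = ih_kinetics(v)
        dq = (q_inf - q) / tau_q
    else:
        dq = 0.0
    if variant.include_spike_currents:
        _, alpha_h, beta_h = fast_na_rates(v)
        alpha_n, beta_n = dr_rates(v)
        dh = alpha_h * (1.0 - h) - beta_h * h
        dn = alpha_n * (1.0 - n) - beta_n * n
    else:
        dh = 0.0
        dn = 0.0
    return np.array([dv, dca, dq, dh, dn])


# ---------------------------------------------------------------------------
# Wang-Buzsaki GABA interneuron
# ---------------------------------------------------------------------------

def wb_rates(v):
    """Wang-Buzsaki rate functions: (m_inf, alpha_h, beta_h, alpha_n, beta_n)."""
    v = np.asarray(v, dtype=float)
    alpha_m = 0.1 * _xexprel(v + 30.0, 10.0)
    beta_m = 4.0 * np.exp(-(v + 55.0) / 18.0)
    m_inf = alpha_m / (alpha_m + beta_m)
    alpha_h = 0.07 * np.exp(-(v + 53.0) / 20.0)
    beta_h = 1.0 / (1.0 + np.exp(-(v + 23.0) / 10.0))
    alpha_n = 0.01 * _xexprel(v + 29.0, 10.0)
    beta_n = 0.0875 * np.exp(-(v + 39.0) / 80.0)
    if v.ndim:
        return m_inf, alpha_h, beta_h, alpha_n, beta_n
    return tuple(float(x) for x in (m_inf, alpha_h, beta_h, alpha_n, beta_n))


def gaba_wb_rhs(state, params: GABAParams, i_syn: float = 0.0):
    """Time derivative of a Wang-Buzsaki interneuron state (v, h, n).

    Na activation is instantaneous (m = m_inf); the K current uses the
    canonical n^4 gating.
    """
    v, h, n = (float(x) for x in state)
    if not np.all(np.isfinite([v, h, n])):
        raise FloatingPointError("non-finite state passed to gaba_wb_rhs")
    m_inf, alpha_h, beta_h, alpha_n, beta_n = wb_rates(v)
    i_total = (params.gbar_Nag * m_inf ** 3 * h * (params.E_Na - v)
               + params.gbar_Kg * n ** 4 * (params.E_K - v)
               + params.g_lg * (params.E_lg - v)
               + params.i_app + i_syn)
    dv = i_total / params.c_m
    dh = alpha_h * (1.0 - h) - beta_h * h
    dn = alpha_n * (1.0 - n) - beta_n * n
    return np.array([dv, dh, dn])


# ---------------------------------------------------------------------------
# Combined ohmic synapse
# ---------------------------------------------------------------------------

def effective_ohmic(g_ampa: float, g_gaba: float,
                    e_ampa: float = 0.0, e_gaba: float = -90.0):
    """Combine AMPA and GABA into one ohmic synapse: (g_eff, E_eff).

    g_eff = g_AMPA + g_GABA and E_eff is the conductance-weighted mean
    reversal potential; with E_AMPA = 0 it reduces to
    E_eff = g_GABA * E_GABA / (g_GABA + g_AMPA).
    """
    if g_ampa < 0 or g_gaba < 0:
        raise ValueError("conductances must be >= 0")
    g_eff = g_ampa + g_gaba
    if g_eff == 0.0:
        raise ValueError("reversal potential undefined for zero total conductance")
    e_eff = (g_ampa * e_ampa + g_gaba * e_gaba) / g_eff
    return g_eff, e_eff
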
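"""Numba-compiled fixed-step RK4 integrators for the DA and GABA models.

These kernels duplicate the rate formulas of :mod:`dopadyn.model_core` in
scalar form for speed; the unit tests cross-check both implementations on a
voltage grid.  Synaptic inputs enter as per-step arrays of *effective*
conductance (maximal conductance times gating); arrays of length 1 are
treated as constants, and ``input_stride`` allows inputs sampled on a
coarser grid than the integration step.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# DAParams packing layout (see pack_da_params)
_NP = 23


def pack_da_params(p) -> np.ndarray:
    """Flatten a DAParams instance into the kernel parameter vector."""
    return np.array([
        p.c_m, p.gbar_Ca, p.gbar_KCa, p.gbar_K, p.gbar_sNa, p.gbar_Na,
        p.gbar_DR, p.g_l, p.g_h, p.E_Ca, p.E_K, p.E_Na, p.E_l, p.E_h,
        p.E_gaba, p.ca_flux_coeff, p.ca_pump_rate, p.ca_leak_frac * p.g_l,
        p.K_sk, p.ca_vhalf, p.ca_k, p.Mg / 3.57, p.m_e,
    ])


def pack_variant(variant) -> np.ndarray:
    return np.array([
        1.0 if variant.include_spike_currents else 0.0,
        1.0 if variant.include_sNa else 0.0,
        1.0 if variant.include_ih else 0.0,
        1.0 if variant.include_ca_leak else 0.0,
    ])


def pack_gaba_params(p) -> np.ndarray:
    return np.array([p.c_m, p.gbar_Nag, p.gbar_Kg, p.g_lg,
                     p.E_Na, p.E_K, p.E_lg, p.i_app])


@njit(cache=False)
def _xexprel(x, k):
    if abs(x) < 1e-7:
        return k + 0.5 * x
    return x / -math.expm1(-x / k)


@njit(cache=False)
def _da_derivs(v, ca, q, h, n, P, F, g_nmda, g_ampa, g_gaba, i_app):
    g_ca = P[1] / (1.0 + math.exp(-(v - P[19]) / P[20]))
    ca4 = ca * ca * ca * ca
    k4 = P[18] ** 4
    g_sk = P[2] * ca4 / (ca4 + k4)
    g_k = P[3] / (1.0 + math.exp(-(v + 10.0) / 7.0))

    i_total = i_app
    i_total += g_ca * (P[9] - v)
    i_total += (g_sk + g_k) * (P[10] - v)
    i_total += P[7] * (P[12] - v)

    if F[1] > 0.0:  # subthreshold Na
        g_sna = P[4] / (1.0 + math.exp(-(v + 50.0) / 5.0))
        i_total += g_sna * (P[11] - v)
    if F[2] > 0.0:  # Ih
        i_total += P[8] * q * (P[13] - v)

    dh = 0.0
    dn = 0.0
    if F[0] > 0.0:  # spike currents
        alpha_m = 0.32 * _xexprel(v + 39.0, 4.0)
        beta_m = 0.28 * _xexprel(-(v + 4.0), 5.0)
        m_inf = alpha_m / (alpha_m + beta_m)
        i_total += P[5] * m_inf ** 3 * h * (P[11] - v)
        i_total += P[6] * n ** 4 * (P[10] - v)
        alpha_h = 0.01 * math.exp(-(v + 47.0) / 18.0)
        beta_h = 1.25 / (1.0 + math.exp(-(v + 24.0) / 5.0))
        alpha_n = 0.0032 * _xexprel(v + 5.0, 10.0)
        beta_n = 0.05 * math.exp(-(v + 10.0) / 16.0)
        dh = alpha_h * (1.0 - h) - beta_h * h
        dn = alpha_n * (1.0 - n) - beta_n * n

    # synaptic currents (E_NMDA = E_AMPA = 0)
    i_total += g_nmda / (1.0 + P[21] * math.exp(-P[22] * v)) * (0.0 - v)
    i_total += g_ampa * (0.0 - v)
    i_total += g_gaba * (P[14] - v)

    dv = i_total / P[0]

    g_ca_total = g_ca
    if F[3] > 0.0:
        g_ca_total += P[17]
    dca = P[15] * g_ca_total * (P[9] - v) - P[16] * ca

    dq = 0.0
    if F[2] > 0.0:
        q_inf = 1.0 / (1.0 + math.exp((v + 95.0) / 8.0))
        tau_q = 625.0 * math.exp(0.075 * (v + 112.0)) / (1.0 + math.exp(0.083 * (v + 112.0)))
        dq = (q_inf - q) / tau_q
    return dv, dca, dq, dh, dn


@njit(cache=False)
def _input_at(arr, i, stride):
    if arr.shape[0] == 1:
        return arr[0]
    j = i // stride
    if j >= arr.shape[0]:
        j = arr.shape[0] - 1
    return arr[j]


@njit(cache=False)
def integrate_da(P, F, y0, dt, n_steps, g_nmda_t, g_ampa_t, g_gaba_t,
                 i_app_t, input_stride, rec_stride):
    """RK4 integration of the DA neuron.

    Returns (rec, n_valid): rec has shape (n_rec, 5) holding
    (v, ca, q, h, n) every ``rec_stride`` steps, including the initial
    state; n_valid is the number of valid records (divergence truncates,
    remaining rows are NaN).
    """
    n_rec = n_steps // rec_stride + 1
    rec = np.full((n_rec, 5), np.nan)
    v, ca, q, h, n = y0[0], y0[1], y0[2], y0[3], y0[4]
    rec[0, 0] = v
    rec[0, 1] = ca
    rec[0, 2] = q
    rec[0, 3] = h
    rec[0, 4] = n
    n_valid = 1
    for i in range(n_steps):
        gn = _input_at(g_nmda_t, i, input_stride)
        ga = _input_at(g_ampa_t, i, input_stride)
        gg = _input_at(g_gaba_t, i, input_stride)
        ia = _input_at(i_app_t, i, input_stride)

        k1 = _da_derivs(v, ca, q, h, n, P, F, gn, ga, gg, ia)
        k2 = _da_derivs(v + 0.5 * dt * k1[0], ca + 0.5 * dt * k1[1],
                        q + 0.5 * dt * k1[2], h + 0.5 * dt * k1[3],
                        n + 0.5 * dt * k1[4], P, F, gn, ga, gg, ia)
        k3 = _da_derivs(v + 0.5 * dt * k2[0], ca + 0.5 * dt * k2[1],
                        q + 0.5 * dt * k2[2], h + 0.5 * dt * k2[3],
                        n + 0.5 * dt * k2[4], P, F, gn, ga, gg, ia)
        k4 = _da_derivs(v + dt * k3[0], ca + dt * k3[1], q + dt * k3[2],
                        h + dt * k3[3], n + dt * k3[4], P, F, gn, ga, gg, ia)
        v += dt / 6.0 * (k1[0] + 2.0 * k2[0] + 2.0 * k3[0] + k4[0])
        ca += dt / 6.0 * (k1[1] + 2.0 * k2[1] + 2.0 * k3[1] + k4[1])
        q += dt / 6.0 * (k1[2] + 2.0 * k2[2] + 2.0 * k3[2] + k4[2])
        h += dt / 6.0 * (k1[3] + 2.0 * k2[3] + 2.0 * k3[3] + k4[3])
        n += dt / 6.0 * (k1[4] + 2.0 * k2[4] + 2.0 * k3[4] + k4[4])
        if ca < 0.0:
            ca = 0.0
        if not (math.isfinite(v) and math.isfinite(ca)):
            return rec, n_valid
        if (i + 1) % rec_stride == 0:
            idx = (i + 1) // rec_stride
            rec[idx, 0] = v
            rec[idx, 1] = ca
            rec[idx, 2] = q
            rec[idx, 3] = h
            rec[idx, 4] = n
            n_valid = idx + 1
    return rec, n_valid


@njit(cache=False)
def da_spike_times(P, F, y0, dt, n_steps, g_nmda_t, g_ampa_t, g_gaba_t,
                   i_app_t, input_stride, threshold, refractory, max_spikes):
    """Integrate and detect threshold upcrossings on the fly.

    Returns (times, count, y_final, ok) where ok = 0 flags divergence.
    """
    times = np.empty(max_spikes)
    count = 0
    v, ca, q, h, n = y0[0], y0[1], y0[2], y0[3], y0[4]
    last_spike = -1.0e12
    ok = 1
    for i in range(n_steps):
        gn = _input_at(g_nmda_t, i, input_stride)
        ga = _input_at(g_ampa_t, i, input_stride)
        gg = _input_at(g_gaba_t, i, input_stride)
        ia = _input_at(i_app_t, i, input_stride)
        v_prev = v
        k1 = _da_derivs(v, ca, q, h, n, P, F, gn, ga, gg, ia)
        k2 = _da_derivs(v + 0.5 * dt * k1[0], ca + 0.5 * dt * k1[1],
                        q + 0.5 * dt * k1[2], h + 0.5 * dt * k1[3],
                        n + 0.5 * dt * k1[4], P, F, gn, ga, gg, ia)
        k3 = _da_derivs(v + 0.5 * dt * k2[0], ca + 0.5 * dt * k2[1],
                        q + 0.5 * dt * k2[2], h + 0.5 * dt * k2[3],
                        n + 0.5 * dt * k2[4], P, F, gn, ga, gg, ia)
        k4 = _da_derivs(v + dt * k3[0], ca + dt * k3[1], q + dt * k3[2],
                        h + dt * k3[3], n + dt * k3[4], P, F, gn, ga, gg, ia)
        v += dt / 6.0 * (k1[0] + 2.0 * k2[0] + 2.0 * k3[0] + k4[0])
        ca += dt / 6.0 * (k1[1] + 2.0 * k2[1] + 2.0 * k3[1] + k4[1])
        q += dt / 6.0 * (k1[2] + 2.0 * k2[2] + 2.0 * k3[2] + k4[2])
        h += dt / 6.0 * (k1[3] + 2.0 * k2[3] + 2.0 * k3[3] + k4[3])
        n += dt / 6.0 * (k1[4] + 2.0 * k2[4] + 2.0 * k3[4] + k4[4])
        if ca < 0.0:
            ca = 0.0
        if not (math.isfinite(v) and math.isfinite(ca)):
            ok = 0
            break
        t = (i + 1) * dt
        if v_prev < threshold <= v and t - last_spike >= refractory:
            if count < max_spikes:
                times[count] = t
                count += 1
            last_spike = t
    y_final = np.array([v, ca, q, h, n])
    return times[:count].copy(), count, y_final, ok


@njit(cache=False)
def _wb_derivs(v, h, n, G, s, tau_act, tau_deact, i_syn):
    alpha_m = 0.1 * _xexprel(v + 30.0, 10.0)
    beta_m = 4.0 * math.exp(-(v + 55.0) / 18.0)
    m_inf = alpha_m / (alpha_m + beta_m)
    alpha_h = 0.07 * math.exp(-(v + 53.0) / 20.0)
    beta_h = 1.0 / (1.0 + math.exp(-(v + 23.0) / 10.0))
    alpha_n = 0.01 * _xexprel(v + 29.0, 10.0)
    beta_n = 0.0875 * math.exp(-(v + 39.0) / 80.0)
    i_total = (G[1] * m_inf ** 3 * h * (G[4] - v)
               + G[2] * n ** 4 * (G[5] - v)
               + G[3] * (G[6] - v) + G[7] + i_syn)
    dv = i_total / G[0]
    dh = alpha_h * (1.0 - h) - beta_h * h
    dn = alpha_n * (1.0 - n) - beta_n * n
    gspike = 1.0 / (1.0 + math.exp(-v / 2.0))
    ds = gspike * (1.0 - s) / tau_act - (1.0 - gspike) * s / tau_deact
    return dv, dh, dn, ds


@njit(cache=False)
def integrate_gaba_population(G_all, y0, dt, n_steps, tau_act, tau_deact,
                              rec_stride):
    """Integrate n independent Wang-Buzsaki neurons with output gating.

    G_all: (n, 8) packed parameter rows; y0: (n, 4) initial (v, h, n, s).
    Returns (s_pop, s_per, counts): population-mean gate trace, per-neuron
    gate traces at rec_stride, and per-neuron spike counts (0 mV crossings).
    """
    n_neur = G_all.shape[0]
    n_rec = n_steps // rec_stride + 1
    s_per = np.empty((n_rec, n_neur))
    counts = np.zeros(n_neur, dtype=np.int64)
    state = y0.copy()
    for j in range(n_neur):
        s_per[0, j] = state[j, 3]
    for i in range(n_steps):
        for j in range(n_neur):
            v, h, n, s = state[j, 0], state[j, 1], state[j, 2], state[j, 3]
            v_prev = v
            k1 = _wb_derivs(v, h, n, G_all[j], s, tau_act, tau_deact, 0.0)
            k2 = _wb_derivs(v + 0.5 * dt * k1[0], h + 0.5 * dt * k1[1],
                            n + 0.5 * dt * k1[2], G_all[j],
                            s + 0.5 * dt * k1[3], tau_act, tau_deact, 0.0)
            k3 = _wb_derivs(v + 0.5 * dt * k2[0], h + 0.5 * dt * k2[1],
                            n + 0.5 * dt * k2[2], G_all[j],
                            s + 0.5 * dt * k2[3], tau_act, tau_deact, 0.0)
            k4 = _wb_derivs(v + dt * k3[0], h + dt * k3[1], n + dt * k3[2],
                            G_all[j], s + dt * k3[3], tau_act, tau_deact, 0.0)
            v += dt / 6.0 * (k1[0] + 2.0 * k2[0] + 2.0 * k3[0] + k4[0])
            h += dt / 6.0 * (k1[1] + 2.0 * k2[1] + 2.0 * k3[1] + k4[1])
            n += dt / 6.0 * (k1[2] + 2.0 * k2[2] + 2.0 * k3[2] + k4[2])
            s += dt / 6.0 * (k1[3] + 2.0 * k2[3] + 2.0 * k3[3] + k4[3])
            if s < 0.0:
                s = 0.0
            elif s > 1.0:
                s = 1.0
            if v_prev < 0.0 <= v:
                counts[j] += 1
            state[j, 0] = v
            state[j, 1] = h
            state[j, 2] = n
            state[j, 3] = s
            if (i + 1) % rec_stride == 0:
                s_per[(i + 1) // rec_stride, j] = s
    s_pop = np.empty(n_rec)
    for k in range(n_rec):
        acc = 0.0
        for j in range(n_neur):
            acc += s_per[k, j]
        s_pop[k] = acc / n_neur
    return s_pop, s_per, counts


@njit(cache=False)
def gating_from_drive(j, dt, tau_act, tau_deact, s0):
    """Exact per-step exponential update of ds/dt = j(1-s)/ta - (1-j)s/td.

    j is a 0/1 drive sampled every dt; within a step the gate relaxes
    exactly (to 1 with tau_act when j=1, to 0 with tau_deact when j=0).
    """
    n = j.shape[0]
    s = np.empty(n + 1)
    s[0] = s0
    ea = math.exp(-dt / tau_act)
    ed = math.exp(-dt / tau_deact)
    for i in range(n):
        if j[i] > 0.5:
            s[i + 1] = 1.0 + (s[i] - 1.0) * ea
        else:
            s[i + 1] = s[i] * ed
    return s


@njit(cache=False)
def ou_recursion(normals, rho, noise_scale, x0):
    """Exact OU update x_{k+1} = rho*x_k + noise_scale*z_k, column-wise.

    normals: (n_steps, m) standard normals; x0: (m,) initial values.
    Returns (n_steps + 1, m) unit-variance OU sample paths.
    """
    n_steps, m = normals.shape
    out = np.empty((n_steps + 1, m))
    for j in range(m):
        out[0, j] = x0[j]
    for i in range(n_steps):
        for j in range(m):
            out[i + 1, j] = rho * out[i, j] + noise_scale * normals[i, j]
    return out
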
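"""Phase-plane and bifurcation analysis of the reduced DA-neuron model.

The reduced model drops the spike-producing currents, leaving a planar
(v, [Ca]) system — three-dimensional (v, [Ca], q) when Ih is included.
Because the calcium and Ih equations each have a unique quasi-steady state
for a given voltage, every equilibrium lies on the one-dimensional curve
(v, ca*(v)[, q_inf(v)]), which reduces equilibrium finding to a scalar
root scan in v.

Transitions from spiking to rest are classified by certificates:

* SNIC - a saddle-node of equilibria appears at the transition and the
  onset firing frequency tends to zero (type I excitability);
* Andronov-Hopf - a complex eigenvalue pair of an existing equilibrium
  crosses the imaginary axis and the cycle amplitude vanishes (type II);
* LC fold - the stable cycle disappears at finite amplitude and frequency
  while a stable equilibrium coexists (hysteresis; type II);
* saddle-node off the cycle - a fold of equilibria that does not destroy
  the cycle (diagnostic only).

Detection is simulation-plus-algebra (bisection on the sweep parameter,
equilibria by root finding, cycles by long integration) rather than a
continuation library, keeping every certificate explicit and testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, fsolve

from . import model_core as mc
from .params import DAParams, ModelVariant
from .simulation_engine import steady_state_rate

__all__ = [
    "Equilibrium", "Nullclines", "BifurcationPoint", "ExcitabilityVerdict",
    "nullclines", "find_equilibria", "equilibrium_branch",
    "classify_transition", "excitability_type", "bt_boundary", "bt_point",
    "bistability_window", "branch_has_fold", "ih_fold_critical_gh",
]

ONSET_EPS_HZ = 0.5          # type I/II onset-frequency threshold
_V_WINDOW = (-100.0, -15.0)  # search window for subthreshold equilibria


# ---------------------------------------------------------------------------
# Quasi-steady-state reductions
# ---------------------------------------------------------------------------

def ca_star(v, params: DAParams, include_ca_leak: bool = True):
    """[Ca] on the calcium nullcline: influx/pump balance at voltage v."""
    g = mc.ca_conductance(v, params)
    if include_ca_leak:
        g = g + params.ca_leak_frac * params.g_l
    return g * (params.E_Ca - v) / (params.z * params.F * params.P_Ca)


def _total_current(v, ca, q, params: DAParams, variant: ModelVariant,
                   g_nmda, g_eff, e_eff, i_app):
    """Membrane current sum of the reduced model (no spike currents)."""
    i = mc.ca_conductance(v, params) * (params.E_Ca - v)
    i += (mc.sk_conductance(ca, params) + mc.k_conductance(v, params)) * (params.E_K - v)
    i += params.g_l * (params.E_l - v)
    if variant.include_sNa:
        i += mc.sna_conductance(v, params) * (params.E_Na - v)
    if variant.include_ih:
        i += params.g_h * q * (params.E_h - v)
    if g_nmda:
        i += mc.nmda_conductance(v, g_nmda, params) * (0.0 - v)
    if g_eff:
        i += g_eff * (e_eff - v)
    return i + i_app


def _reduced_rhs(y, params, variant, g_nmda, g_eff, e_eff, i_app):
    """(dv, dca[, dq]) of the reduced system."""
    if variant.include_ih:
        v, ca, q = y
    else:
        v, ca = y
        q = 0.0
    ca = max(ca, 0.0)  # finite-difference probes may dip below zero
    dv = _total_current(v, ca, q, params, variant, g_nmda, g_eff, e_eff,
                        i_app) / params.c_m
    g_ca_tot = mc.ca_conductance(v, params)
    if variant.include_ca_leak:
        g_ca_tot += params.ca_leak_frac * params.g_l
    dca = (params.ca_flux_coeff * g_ca_tot * (params.E_Ca - v)
           - params.ca_pump_rate * ca)
    if not variant.include_ih:
        return np.array([dv, dca])
    q_inf, tau_q = mc.ih_kinetics(v)
    return np.array([dv, dca, (q_inf - q) / tau_q])


def _jacobian(y, params, variant, g_nmda, g_eff, e_eff, i_app,
              eps=1e-6) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    n = y.size
    J = np.empty((n, n))
    for j in range(n):
        step = eps * max(1.0, abs(y[j]))
        yp = y.copy(); yp[j] += step
        ym = y.copy(); ym[j] -= step
        fp = _reduced_rhs(yp, params, variant, g_nmda, g_eff, e_eff, i_app)
        fm = _reduced_rhs(ym, params, variant, g_nmda, g_eff, e_eff, i_app)
        J[:, j] = (fp - fm) / (2.0 * step)
    return J


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class Equilibrium:
    state: np.ndarray            # (v, ca[, q])
    eigenvalues: np.ndarray
    stability: str               # stable_node | stable_focus | saddle | unstable
    residual: float

    @property
    def v(self) -> float:
        return float(self.state[0])

    @property
    def is_stable(self) -> bool:
        return self.stability.startswith("stable")


@dataclass
class Nullclines:
    v: np.ndarray                # voltage grid
    ca_nullcline: np.ndarray     # ca*(v)
    v_nullcline_v: np.ndarray    # points (v, ca) with dv/dt = 0
    v_nullcline_ca: np.ndarray


@dataclass
class BifurcationPoint:
    kind: str                    # SNIC | AndronovHopf | SaddleNode | LCFold | none
    param: str
    value: float
    onset_rate_hz: float = np.nan
    eigenvalues: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)


@dataclass
class ExcitabilityVerdict:
    type: str                    # "I" or "II"
    onset_rate_hz: float
    transition: str | None = None
    param_at_transition: float = np.nan


# ---------------------------------------------------------------------------
# Nullclines and equilibria
# ---------------------------------------------------------------------------

def nullclines(params: DAParams, variant: ModelVariant | None = None, *,
               g_nmda: float = 0.0, g_eff: float = 0.0, e_eff: float = -90.0,
               i_app: float = 0.0, v_range=(-90.0, -20.0), n_points: int = 400,
               ca_max: float | None = None) -> Nullclines:
    """Voltage and calcium nullclines of the reduced planar system.

    With Ih included, q is held at quasi-steady state q_inf(v) and the
    curves are drawn on the (v, ca) plane.  The v-nullcline is obtained by
    solving the SK balance for ca at each voltage (it may be empty at
    voltages where no calcium level nulls the current).
    """
    variant = variant or ModelVariant.reduced()
    if variant.include_spike_currents:
        raise ValueError("nullclines require a reduced (no-spike) variant")
    lo, hi = v_range
    if not lo < hi:
        raise ValueError("empty voltage window")
    v = np.linspace(lo, hi, n_points)
    can = ca_star(v, params, variant.include_ca_leak)
    if ca_max is None:
        ca_max = max(10.0 * params.K_sk, 2.0 * float(np.nanmax(can)))
    vn_v, vn_ca = [], []
    for vv in v:
        q = mc.ih_kinetics(vv)[0] if variant.include_ih else 0.0

        def f(ca):
            return _total_current(vv, ca, q, params, variant,
                                  g_nmda, g_eff, e_eff, i_app)

        f0, f1 = f(0.0), f(ca_max)
        if f0 == 0.0:
            vn_v.append(vv); vn_ca.append(0.0)
        elif f0 * f1 < 0:
            vn_v.append(vv)
            vn_ca.append(brentq(f, 0.0, ca_max, xtol=1e-12))
    return Nullclines(v=v, ca_nullcline=can,
                      v_nullcline_v=np.array(vn_v),
                      v_nullcline_ca=np.array(vn_ca))


def find_equilibria(params: DAParams, variant: ModelVariant | None = None, *,
                    g_nmda: float = 0.0, g_eff: float = 0.0,
                    e_eff: float = -90.0, i_app: float = 0.0,
                    v_window=_V_WINDOW, n_scan: int = 2000
                    ) -> list[Equilibrium]:
    """All equilibria of the reduced model under tonic input.

    Every equilibrium satisfies ca = ca*(v) (and q = q_inf(v)), so roots
    are located by a dense scalar scan of the residual current along that
    curve, refined by Brent's method, then classified by the Jacobian
    eigenvalues of the full reduced system.
    """
    variant = variant or ModelVariant.reduced()
    if variant.include_spike_currents:
        raise ValueError("equilibrium analysis uses the reduced variant")

    def residual(v):
        ca = ca_star(v, params, variant.include_ca_leak)
        q = mc.ih_kinetics(v)[0] if variant.include_ih else 0.0
        return _total_current(v, ca, q, params, variant, g_nmda, g_eff,
                              e_eff, i_app)

    vs = np.linspace(v_window[0], v_window[1], n_scan)
    res = np.array([residual(v) for v in vs])
    out: list[Equilibrium] = []
    for i in np.flatnonzero(np.sign(res[:-1]) * np.sign(res[1:]) < 0):
        v_root = brentq(residual, vs[i], vs[i + 1], xtol=1e-12)
        ca = ca_star(v_root, params, variant.include_ca_leak)
        y = [v_root, ca]
        if variant.include_ih:
            y.append(mc.ih_kinetics(v_root)[0])
        y = np.array(y)
        J = _jacobian(y, params, variant, g_nmda, g_eff, e_eff, i_app)
        eig = np.linalg.eigvals(J)
        out.append(Equilibrium(state=y, eigenvalues=eig,
                               stability=_classify_eigs(eig),
                               residual=abs(residual(v_root))))
    return out


def _classify_eigs(eig: np.ndarray) -> str:
    re = np.real(eig)
    if np.all(re < 0):
        return "stable_focus" if np.any(np.abs(np.imag(eig)) > 0) else "stable_node"
    if np.all(re > 0):
        return "unstable"
    return "saddle"


def equilibrium_branch(params: DAParams, variant: ModelVariant, *,
                       g_nmda: float = 0.0, g_eff_of_v=None,
                       e_eff: float = -90.0,
                       v_grid: np.ndarray) -> np.ndarray:
    """i_app required to place an equilibrium at each voltage of v_grid.

    Parameterizing the equilibrium branch by voltage avoids continuation:
    folds of the branch in the (i_app, v) plane are exactly the sign
    changes of d i_app / dv.
    """
    out = np.empty(v_grid.size)
    for i, v in enumerate(v_grid):
        ca = ca_star(v, params, variant.include_ca_leak)
        q = mc.ih_kinetics(v)[0] if variant.include_ih else 0.0
        out[i] = -_total_current(v, ca, q, params, variant, g_nmda,
                                 0.0, e_eff, 0.0)
    return out


def branch_has_fold(params: DAParams, variant: ModelVariant, *,
                    v_grid: np.ndarray | None = None) -> bool:
    """True iff the equilibrium branch v -> i_app(v) is non-monotonic."""
    if v_grid is None:
        v_grid = np.linspace(-90.0, -25.0, 600)
    i_of_v = equilibrium_branch(params, variant, v_grid=v_grid)
    d = np.diff(i_of_v)
    return bool(np.any(d > 0) and np.any(d < 0))


def ih_fold_critical_gh(params: DAParams, *, gh_max: float = 12.0,
                        tol: float = 1e-3) -> float:
    """Critical Ih conductance above which the equilibrium folds vanish.

    The reduced model with Ih (q at steady state on the branch) has an
    S-shaped equilibrium curve versus applied current at small g_h; Ih
    straightens it.  Bisects g_h on the fold-existence predicate.
    """
    variant = ModelVariant.reduced(include_ih=True)
    lo, hi = 0.0, gh_max
    if not branch_has_fold(params.replace(g_h=lo), variant):
        raise ValueError("no fold at g_h = 0; cannot bracket")
    if branch_has_fold(params.replace(g_h=hi), variant):
        raise ValueError(f"fold persists at g_h = {gh_max}")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if branch_has_fold(params.replace(g_h=mid), variant):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Transition classification
# ---------------------------------------------------------------------------

def _rate_at(params, variant, param, value, extra, duration, transient):
    drive = dict(extra or {})
    drive[param] = value
    return steady_state_rate(params, variant, duration=duration,
                             transient=transient, **drive)


def _analysis_kwargs(param, value, extra):
    kw = {"g_nmda": 0.0, "g_eff": 0.0, "e_eff": -90.0, "i_app": 0.0}
    d = dict(extra or {})
    d[param] = value
    for k, v in d.items():
        if k == "g_gaba":
            kw["g_eff"] += v
            kw["e_eff"] = -90.0
        elif k == "g_eff":
            kw["g_eff"] += v
        elif k in kw:
            kw[k] = v
        else:
            raise ValueError(f"unsupported analysis drive: {k}")
    return kw


def classify_transition(params: DAParams, variant: ModelVariant, param: str,
                        grid: np.ndarray, *, extra_drive: dict | None = None,
                        duration: float = 10000.0, transient: float = 2000.0,
                        onset_duration: float = 30000.0,
                        refine_tol: float | None = None,
                        onset_eps_hz: float = ONSET_EPS_HZ
                        ) -> BifurcationPoint:
    """Locate and classify the spiking-to-rest transition along ``param``.

    The grid must bracket the transition (spiking at one end, rest at the
    other; spiking is assumed at the low end, as for GABA/hyperpolarizing
    sweeps).  Bisection localizes the critical value; certificates decide:

    * onset rate below ``onset_eps_hz`` AND a new equilibrium pair at the
      critical parameter -> SNIC;
    * finite onset rate, equilibrium persists on both sides and its
      leading complex pair crosses Re = 0 -> Andronov-Hopf;
    * finite onset rate with a stable equilibrium coexisting on the
      spiking side (hysteresis) -> LCFold.
    """
    grid = np.asarray(grid, dtype=float)
    lo, hi = float(grid[0]), float(grid[-1])
    rate_lo = _rate_at(params, variant, param, lo, extra_drive, duration, transient)
    rate_hi = _rate_at(params, variant, param, hi, extra_drive, duration, transient)
    if (rate_lo > 0) == (rate_hi > 0):
        return BifurcationPoint(kind="none", param=param, value=np.nan,
                                diagnostics={"rate_lo": rate_lo,
                                             "rate_hi": rate_hi})
    if rate_lo == 0:   # normalize: spiking at lo
        lo, hi = hi, lo
    tol = refine_tol or abs(hi - lo) * 1e-3
    a, b = lo, hi
    while abs(b - a) > tol:
        midv = 0.5 * (a + b)
        r = _rate_at(params, variant, param, midv, extra_drive, duration,
                     transient)
        if r > 0:
            a = midv
        else:
            b = midv
    p_c = 0.5 * (a + b)
    span = abs(hi - lo)
    onset = _rate_at(params, variant, param, a, extra_drive,
                     onset_duration, transient)

    if variant.include_spike_currents:
        # no planar equilibrium certificates for the full model: the verdict
        # rests on the onset frequency alone
        kind = "SNIC" if onset < onset_eps_hz else "AndronovHopf"
        return BifurcationPoint(kind=kind, param=param, value=p_c,
                                onset_rate_hz=onset,
                                diagnostics={"onset_rate": onset,
                                             "certificates": "onset-only"})

    step = max(5.0 * tol, 1e-3 * span) * np.sign(hi - lo)
    eq_spk = find_equilibria(params, variant,
                             **_analysis_kwargs(param, p_c - step, extra_drive))
    eq_rest = find_equilibria(params, variant,
                              **_analysis_kwargs(param, p_c + step, extra_drive))
    n_stable_spk = sum(e.is_stable for e in eq_spk)
    new_pair = len(eq_rest) >= len(eq_spk) + 2
    diag = {"onset_rate": onset, "n_eq_spiking": len(eq_spk),
            "n_eq_rest": len(eq_rest), "n_stable_spiking": n_stable_spk}
    eig = eq_rest[0].eigenvalues if eq_rest else None

    if onset < onset_eps_hz and new_pair:
        kind = "SNIC"
    elif n_stable_spk > 0:
        kind = "LCFold"
    elif new_pair:
        kind = "SaddleNode"
    else:
        kind = "AndronovHopf"
    return BifurcationPoint(kind=kind, param=param, value=p_c,
                            onset_rate_hz=onset, eigenvalues=eig,
                            diagnostics=diag)


def excitability_type(fi, eps: float = ONSET_EPS_HZ) -> ExcitabilityVerdict:
    """Type I/II verdict from an F-I (or F-conductance) curve.

    Type I iff the firing rate at the last spiking point before quiescence
    falls below ``eps`` (continuous frequency decrease to zero); type II
    records the discontinuous jump size.
    """
    rates = np.asarray(fi.rates, dtype=float)
    spiking = rates > 0
    if spiking.all() or not spiking.any():
        raise ValueError("curve must span the firing onset")
    idx = np.flatnonzero(spiking[:-1] != spiking[1:])
    # onset rate: last spiking point adjacent to a quiescent one
    onset_rates = []
    for i in idx:
        onset_rates.append(rates[i] if spiking[i] else rates[i + 1])
    onset = float(min(onset_rates))
    k = idx[int(np.argmin(onset_rates))]
    return ExcitabilityVerdict(type="I" if onset < eps else "II",
                               onset_rate_hz=onset,
                               param_at_transition=float(fi.values[k]))


# ---------------------------------------------------------------------------
# Bogdanov-Takens boundary
# ---------------------------------------------------------------------------

def bt_point(params: DAParams, *, g_nmda: float = 0.0,
             x0=(-62.0, -75.0)) -> tuple[float, float, float]:
    """Direct Bogdanov-Takens point of the reduced planar model.

    Solves for the voltage v and ohmic reversal potential E_eff at which
    the equilibrium branch versus g_eff has a fold (d g_eff/dv = 0) while
    the Jacobian trace vanishes - the double-zero eigenvalue condition.
    Returns (e_eff_bt, g_eff_bt, v_bt).
    """
    variant = ModelVariant.reduced()

    def g_eff_for(v, e_eff):
        ca = ca_star(v, params)
        i0 = _total_current(v, ca, 0.0, params, variant, g_nmda, 0.0, e_eff, 0.0)
        return i0 / (v - e_eff)

    def conditions(x):
        v, e_eff = x
        g = g_eff_for(v, e_eff)
        dv = 1e-4
        gp = g_eff_for(v + dv, e_eff)
        gm = g_eff_for(v - dv, e_eff)
        fold = (gp - gm) / (2 * dv)
        y = np.array([v, ca_star(v, params)])
        J = _jacobian(y, params, variant, g_nmda, g, e_eff, 0.0)
        return [fold, np.trace(J)]

    starts = [x0] + [(v0, e0) for v0 in (-65.0, -60.0, -55.0, -50.0, -45.0)
                     for e0 in (-90.0, -80.0, -70.0, -60.0)]
    for s in starts:
        x, info, ier, _ = fsolve(conditions, s, full_output=True)
        if ier != 1:
            continue
        v_bt, e_bt = x
        g_bt = g_eff_for(v_bt, e_bt)
        if g_bt <= 0 or not (-110.0 < e_bt < -20.0) or not (-90.0 < v_bt < -20.0):
            continue
        return float(e_bt), float(g_bt), float(v_bt)
    raise RuntimeError("BT root search did not converge")


def bt_boundary(params: DAParams, *, g_nmda: float = 0.0,
                e_grid=(-90.0, -60.0), tol: float = 0.25,
                g_eff_max: float = 20.0, duration: float = 15000.0,
                onset_duration: float = 60000.0,
                refine_tol: float = 0.004) -> float:
    """E_eff at which the spiking-to-rest transition changes type.

    For each reversal potential the combined ohmic conductance g_eff is
    grown until firing stops; the onset frequency at the critical point
    yields the verdict (SNIC/type I at low E_eff, Hopf/type II at high).
    The flip point is bisected to ``tol`` mV and cross-checked in the
    tests against the algebraic double-zero condition (:func:`bt_point`).
    """
    variant = ModelVariant.reduced()

    def is_type_one(e_eff) -> bool:
        bp = classify_transition(
            params, variant, "g_eff", np.array([0.0, g_eff_max]),
            extra_drive={"e_eff": e_eff}, duration=duration,
            onset_duration=onset_duration, refine_tol=refine_tol)
        if bp.kind == "none":
            raise RuntimeError(f"no transition up to g_eff={g_eff_max} "
                               f"at E_eff={e_eff}")
        return bp.onset_rate_hz < ONSET_EPS_HZ

    lo, hi = e_grid
    if not is_type_one(lo):
        raise ValueError(f"expected a type I transition at E_eff = {lo}")
    if is_type_one(hi):
        raise ValueError(f"expected a type II transition at E_eff = {hi}")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if is_type_one(mid):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def bistability_window(params: DAParams, variant: ModelVariant, *,
                       i_range: tuple[float, float], n_points: int = 60,
                       duration: float = 8000.0,
                       extra_drive: dict | None = None) -> float:
    """Width (in current units) of spiking/rest coexistence.

    Runs rising and falling hyperpolarizing-current ramps (state carried
    between points) and returns the distance between the rising-onset and
    falling-offset currents; zero when the two F-I branches agree.
    """
    from .simulation_engine import fi_curve
    grid = np.linspace(i_range[0], i_range[1], n_points)
    up = fi_curve(params, variant, "i_app", grid, direction="rising",
                  duration=duration, extra_drive=extra_drive)
    down = fi_curve(params, variant, "i_app", grid, direction="falling",
                    duration=duration, extra_drive=extra_drive)
    up_on = up.rates > 0
    down_on = down.rates > 0
    if up_on.all() or not up_on.any() or down_on.all() or not down_on.any():
        raise ValueError("current range must span the firing onset")
    # onset: most hyperpolarized current at which each branch still spikes
    i_up = grid[np.flatnonzero(up_on)[0]]
    i_down = grid[np.flatnonzero(down_on)[0]]
    return float(abs(i_up - i_down))
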
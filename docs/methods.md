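# Methods

## The model

`dopadyn` implements a single-compartment conductance-based model of a
midbrain (SNc-type) dopamine neuron.  Membrane voltage obeys

```
c_m dv/dt = I_Ca + I_KCa + I_K + I_DR + I_sNa + I_Na + I_leak + I_h
            + I_NMDA + I_AMPA + I_GABA + I_app
```

with an instantaneously gated L-type calcium current, an SK-type
calcium-dependent potassium current (Hill coefficient 4 in [Ca]), a
Boltzmann-gated potassium current, spike-producing fast Na and
delayed-rectifier K currents (Hodgkin-Huxley kinetics, instantaneous Na
activation), a persistent subthreshold Na current (instantaneous, no state
variable), a hyperpolarization-activated cation current Ih (first-order
activation `q`, half-activation −95 mV, voltage-dependent time constant
peaking at 312.5 ms), and an ohmic leak whose reversal (−35 mV) stands in
for the depolarizing nonselective cation currents of DA neurons.

Calcium balances L-type influx (plus a small calcium component of the
leak, fraction 0.1 of `g_l`) against a linear pump:

```
d[Ca]/dt = (2*beta/r) * ( (g_Ca(v) + 0.1*g_l) * (E_Ca - v) / (z*F) - P_Ca*[Ca] )
```

With voltages in mV, conductances in mS/cm², time in ms, `r` in cm and `F`
in C/mol this yields µM/ms with no extra conversion constant; the pump
rate `P_Ca` carries cm/ms.  Calcium entry through NMDA receptors is
omitted (spatial segregation of NMDARs and SK channels).

The pacemaking core is the subthreshold Ca–SK relaxation oscillation:
calcium accumulates while the cell is depolarized, the SK current
repolarizes it, and the slow pump clearance (time constant
`1/((2β/r)P_Ca)` ≈ 870 ms) sets the 1–5 Hz background rhythm.  The
spike-producing currents add an action potential per subthreshold
oscillation maximum without materially changing the rate; the *reduced*
model removes them and registers spikes as upward crossings of −40 mV
(0 mV in the full model), each with a 2 ms refractory guard.

## Synaptic currents and the NMDA Mg block

AMPA and GABA receptor currents are ohmic (`E_AMPA = 0`,
`E_GABA = −90 mV`).  The NMDA conductance carries the Jahr–Stevens
magnesium block

```
g_NMDA(v) = gbar_NMDA / (1 + ([Mg]/3.57) * exp(-0.062 v)),   [Mg] = 0.5 mM
```

The prefactor matters quantitatively: with it, the ohmic trade-off ratio
`(v - E_GABA) / (−v · block(v))` — the number of NMDA conductance units
one GABA unit cancels — is 3.40 ± 0.05 across the whole subthreshold
range (−65…−55 mV).  This is what makes tonic NMDA and GABA
*compensable*: at `g_NMDA = 16.9`, `g_GABA = 5 mS/cm²` the two currents
nearly cancel through the interspike trajectory, producing the slow
"bottleneck" and ~1.4 Hz balanced firing, and it fixes the slope of the
balanced band on the conductance plane at ≈ 3.4 independently of most
other details.  A much weaker block (e.g. a 0.05 prefactor) makes the
balanced state unreachable at these conductances; we therefore regard the
Jahr–Stevens form as the intended one.

Receptor gating follows first-order on/off kinetics
(`τ_act/τ_deact`: AMPA 1/1.6 ms, NMDA 7/170 ms, GABA 0.08/10 ms).  Tonic
drive corresponds to gating pinned at 1, the reduction used throughout
the sweeps (it mimics dynamic-clamp conductance injection).

## Synthetic inputs

* **Glutamate**: 35 independent Poisson spike trains at ~10 Hz.  NMDARs
  are activated only by coincidences — at least 2 spikes of the pooled
  train within a 1 ms window trigger a 1 ms unit pulse of the drive
  (window and threshold are config-exposed).
* **GABA population**: 30 Wang–Buzsáki fast-spiking interneurons
  (canonical m³h / n⁴ gating; the printed rate functions, which are
  shifted a few mV from the 1996 original, are used as printed).  Each
  neuron's applied current is drawn uniformly from the calibrated
  interval mapping to 12–22 Hz (−0.268…−0.1305 µA/cm²; the printed
  variant is intrinsically active at ≈26 Hz with zero current, so the
  band requires slight hyperpolarization).  Output gates driven by
  `gspike(v) = 1/(1+exp(−v/2))` are averaged over the population, giving
  quasi-constant inhibition (trace CV < 0.3 for 30 neurons).
* **Correlated OU drive**: per-neuron NMDA conductance
  `g_i = μ + σ(√(1−c)·x_i + √c·x_c)` with unit-variance OU processes
  (exact discretization, stationary start), defaults μ = 1.5,
  σ = 0.5 mS/cm², c = 0.5, τ = 5 ms.  The √-weighting (rather than
  linear weights) preserves the stationary sd σ and makes the pairwise
  trace correlation equal c.  Negative excursions are clipped at zero.
  A multiplicative 1 Hz sine envelope models slow-modulated drive.

Asynchronous drive activates the receptors nearly tonically; comparisons
against the tonic reduction rescale the asynchronous maximal
conductances by the mean gating (the population GABA gate averages well
below 1).  At matched mean effective conductance the tonic reduction
reproduces asynchronous rates up to a fluctuation-driven excess of
~1.2–1.7× in this calibration: upward conductance excursions recruit the
regenerative NMDA response asymmetrically, adding both rate and ISI
irregularity.

## Calibration

Table parameters (capacitance, maximal conductances, reversals, receptor
time constants) are taken as printed in the shipped `table1.yaml`.  The
calcium-handling constants and the L-type activation curve are not
printed anywhere and were calibrated, once, against the five quantitative
anchors of the study (balanced-state rate 1.5 Hz at (16.9, 5); balance
slope 3.4; AMPA-driven ceiling ≤ 10 Hz; type I/II boundary at
E_eff ≈ −72.26 mV; Ih cusp at g_h ≈ 7 mS/cm²) plus the 1–5 Hz background
band:

| constant | value | meaning |
|---|---|---|
| `ca_vhalf` | −42 mV | L-type activation midpoint |
| `ca_k` | 6 mV | L-type activation slope |
| `K_sk` | 78 µM | SK half-activation [Ca] |
| `P_Ca` | 2.56e−6 cm/ms | pump removal rate |
| `beta_ca` | 0.045 | free/total Ca ratio |
| `r` | 2 µm | compartment radius |
| `E_h` | −25 mV | Ih reversal |

The activation *threshold* of the L-type current (5–20% activation)
falls at −55…−50 mV, honoring the low L-type threshold of DA cells; the
midpoint itself must sit higher, because the equilibrium branch of the
reduced model has to be gentle enough (max slope ≈ +0.2 mS/cm² near
−60…−55 mV) for a 7 mS/cm² Ih conductance to straighten it — a steep
activation near −50 produces a fold of slope ~+20 that no Ih can remove.
Calcium concentrations in this parameterization are "model units": tens
of µM at depolarized voltages, which should be read as concentrations in
an effective shell volume rather than bulk cytosol.

## Bifurcation analysis and excitability typing

All phase-plane work uses the reduced model.  Because calcium (and the
Ih gate) have unique quasi-steady states at fixed voltage, every
equilibrium lies on the curve `(v, ca*(v)[, q_inf(v)])`, so equilibria
are found by a dense scalar root scan in `v` (residual < 1e−8), and the
equilibrium branch versus applied current is obtained in closed form by
evaluating `i_app(v) = −I_total(v, ca*(v), q_inf(v))` — folds of the
branch are sign changes of its derivative, with no continuation package
involved.

Transitions from spiking to rest are localized by bisection on the sweep
parameter and classified by certificates: a new equilibrium pair plus a
vanishing onset frequency indicates a SNIC; a persisting equilibrium with
finite onset indicates an Andronov–Hopf; a stable equilibrium coexisting
on the spiking side indicates a limit-cycle fold with hysteresis.  The
*type verdict* itself uses the operational criterion: type I iff the
firing rate at the last spiking point is below ε = 0.5 Hz (resolved with
60 s onset simulations and parameter steps of ~4e−3).

In this calibration the SK feedback slightly exceeds the pump rate at the
saddle-node folds, so the node is born weakly unstable: the cycle dies by
slow passage with onset frequencies of 0.2–0.45 Hz (operationally type I)
rather than through a textbook SNIC.  Two consequences are documented
rather than hidden: the onset frequency does not follow the square-root
law (measured log–log slope ≈ 0.25), and near the Ih cusp the transition
is degenerate-slow with no measurable hysteresis window.  Removing the
small subthreshold Na current also leaves the verdict type I here: the
shallow L-type tail supplies the regenerative subthreshold slope that the
original account attributes to the sNa current.  A constrained search for
parameter sets that restore these three properties while keeping the five
quantitative anchors returned no candidates; the anchors were given
precedence.

The type I/II boundary of the combined ohmic synapse
(`g_eff = g_AMPA + g_GABA`, `E_eff` the conductance-weighted reversal) is
found by bisecting `E_eff` on the onset-frequency verdict; the shipped
calibration yields ≈ −73.0 mV with NMDA absent (the strict saddle-node
existence boundary lies at ≈ −85 mV; both are reported by the analysis,
the onset-based one being the observable "type" boundary).

## Depolarization block

Block is declared when a post-transient trace has no spikes, mean voltage
above −55 mV and peak-to-peak amplitude below 5 mV.  The −55 mV cutoff
separates the depolarized quiescent states (NMDA block ≈ −32 mV;
AMPA-shunted rest ≈ −52 mV) from hyperpolarized pauses (GABA rest
−70…−82 mV).  GABA co-activation rescues firing from NMDA-induced block
(a window of tonic firing reopens at g_GABA ≈ 5 for g_NMDA = 16.9); no
amount of GABA rescues AMPA-induced silencing, and the AMPA-driven rate
never exceeds ~5 Hz before silencing.

## Population simulations and dopamine release

Populations of 50 neurons (leak conductance uniform ±15% around nominal,
keeping all neurons tonically active) receive correlated OU NMDA drive.
Synaptic dopamine follows impulsive release (0.1 µM per pooled spike)
with Michaelis–Menten uptake (V_max = 0.004 µM/ms, K_m = 0.2 µM).  For
regular spiking at rate f the continuous flux balance
`[DA]* = K_m·R/(V_max − R)`, `R = 0.1·f/1000`, is a lower bound on the
time-averaged concentration; with impulsive release the exact cycle
average follows from integrating the uptake ODE between spikes
(`mean = (K_m·Δ + Δ(x₀+x₁)/2)/(V_max·T)` with jump Δ = 0.1 µM and
periodic endpoints x₀ = x₁ + Δ) and exceeds the continuous value by
12–21% at 1–4 Hz because x/(K_m+x) is concave.  Simulation matches the
exact pulsed form within 1%.  Synchrony is quantified as the variance of the binned
(20 ms) summed spike count divided by its expectation over circularly
time-shifted rasters (≈1 for asynchronous populations).  Background-tone
conditions add tonic AMPA with GABA bisected so that the population mean
rate under the fluctuating drive stays within 10% of control (shipped
values g_AMPA = 0.5 / g_GABA = 1.6 mS/cm²); the EtOH condition uses
g_AMPA = 0.2, g_GABA = 0.86 and g_h = 1 mS/cm² under 1 Hz sine-modulated
drive.  Tone values are not printed in the source material and live in
the shipped protocol configs.

Under asynchronous drive the low-frequency balanced band sits at lower
conductances than under the tonic reduction (upward conductance
fluctuations recruit the regenerative NMDA response asymmetrically), so
balanced asynchronous cells are identified by their measured rate
(1–5 Hz); within that band the ISI CV stays below 0.5.

## Numerical choices

Fixed-step RK4 (numba-compiled), dt = 0.02 ms for the full model and
0.05 ms for reduced variants; halving dt changes 10 s spike counts by at
most one.  Sweeps use 10 s per point after a 2 s transient; state is
carried between points in hysteresis ramps.  Calcium is clipped at zero;
non-finite states truncate the trajectory and are flagged rather than
raised.  The balance-plane grid is 20×20 over g_NMDA ∈ [0, 40],
g_GABA ∈ [0, 6] mS/cm² — wide enough that the low-rate band (anchored at
the reference cell's rate ±50%) is not clipped by the grid edge, which
would bias the fitted slope downward.  All stochastic generators take
explicit seeds and are bit-reproducible.

## What the synthetic inputs do not capture

Poisson glutamate trains and Wang–Buzsáki interneuron drive emulate
stationary asynchronous background, not structured afferent bursts;
receptor kinetics are single-exponential per branch (no desensitization
beyond the AMPA two-gate approximation, no short-term plasticity); the
dopamine model describes a lumped extrasynaptic concentration without
diffusion or D2 autoreceptor feedback.  Passing tests therefore show
internal consistency of the model and its analyses, not fidelity to any
particular in vivo recording.
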
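# dopadyn

Conductance-based modelling of midbrain dopamine (DA) neuron excitability:
how intrinsic currents and tonic synaptic conductances move the neuron
between type I excitability (firing that slows smoothly to arbitrarily low
rates — a SNIC-type transition) and type II (an abrupt jump to quiescence —
Andronov–Hopf / limit-cycle-fold transitions), and what that switch does to
population dopamine release.

The package is aimed at computational neuroscientists who want a tested,
scriptable reimplementation of this analysis: a single-compartment
Hodgkin–Huxley-style DA neuron whose pacemaking rests on an L-type Ca²⁺ /
SK K⁺ subthreshold oscillator, with subthreshold Na⁺, Ih, spike currents,
and NMDA/AMPA/GABA synapses:

```
c_m dv/dt = g_Ca(v)(E_Ca−v) + [g_SK([Ca]) + g_K(v) + ḡ_DR n⁴](E_K−v)
            + [g_sNa(v) + ḡ_Na m∞³h](E_Na−v) + g_l(E_l−v) + g_h q(E_h−v)
            + g_NMDA(v)s_N(0−v) + g_AMPA s_A(0−v) + g_GABA s_G(E_GABA−v) + I_app

d[Ca]/dt  = (2β/r)[(g_Ca(v) + 0.1 g_l)(E_Ca−v)/(zF) − P_Ca [Ca]]
```

Alongside the model it provides the input generators (Poisson glutamate
trains with an NMDA coincidence threshold, a Wang–Buzsáki GABA interneuron
population, correlated Ornstein–Uhlenbeck NMDA drive), sweep and
spike-statistics machinery, phase-plane/bifurcation analysis with
excitability-type verdicts, and heterogeneous-population simulations with
Michaelis–Menten dopamine release.

## Worked example

```python
import numpy as np
from dopadyn import default_params, ModelVariant, integrate, firing_stats

params = default_params()            # shipped calibrated parameter set
full = ModelVariant.full()

# background pacemaking (no synaptic input)
bg = integrate(params, full, 12000, transient=2000)
rate, _ = firing_stats(bg.post_transient_spikes, min_isis=2)
print(f"background rate: {rate:.2f} Hz")

# balanced tonic NMDA + GABA co-activation
bal = integrate(params, full, 12000, g_nmda=16.9, g_gaba=5.0, transient=2000)
rate_b, _ = firing_stats(bal.post_transient_spikes, min_isis=2)
print(f"balanced-state rate: {rate_b:.2f} Hz")

# removing excitation from the balanced state -> pause
from dopadyn import depolarization_block_detect
pause = integrate(params, full, 6000, g_gaba=5.0, transient=0,
                  y0=bal.final_state)
print(f"spikes after NMDA removal: {pause.spike_times.size}")

# the same NMDA conductance alone drives depolarization block,
# which GABA co-activation rescues
blocked = integrate(params, full, 10000, g_nmda=16.9, transient=2000)
print(f"NMDA alone blocked: {depolarization_block_detect(blocked)}")
```

prints

```
background rate: 1.38 Hz
balanced-state rate: 1.38 Hz
spikes after NMDA removal: 0
NMDA alone blocked: True
```

The neuron fires at background-like rates (1–5 Hz band) even though both
synaptic conductances are large: NMDA excitation and GABA inhibition
cancel along a ~3.4 : 1 line on the conductance plane.  Removing either
partner breaks the balance — dropping NMDA leaves a GABA-dominated pause,
while the same NMDA conductance alone pins the membrane in depolarization
block, from which tonic GABA rescues regular firing.

The numbered scripts under `analysis/` run the full study: the
NMDA–GABA balance plane and rescue from depolarization block
(`01_balance_plane.py`), asynchronous versus tonic drive
(`02_asynchronous_inputs.py`), excitability typing and the type I/II
boundary (`03_excitability_types.py`), Ih-induced changes of the
equilibrium structure (`04_ih_bifurcations.py`), and population dopamine
release under background tone and an EtOH-like condition
(`05_population_release.py`).  Each writes tidy CSV/JSON under
`results/`.  The same protocols are available declaratively:
`dopadyn run fig2 --out results` (configs `fig1`…`fig13`, `s1`…`s3`,
`calibration` ship with the package).

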
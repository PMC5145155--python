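# Canonical DA-neuron parameter set: printed model parameters plus the
# calibrated calcium-handling and L-type activation constants of this package
# (see docs/methods.md, "Calibration").  Units: mV, ms, mS/cm^2, uF/cm^2, uM.
c_m: 1.0
gbar_K: 1.0
gbar_Ca: 2.5
gbar_KCa: 7.8
gbar_sNa: 0.13
g_l: 0.18
gbar_Na: 50.0
gbar_DR: 2.0
g_h: 0.0
E_K: -90.0
E_Ca: 50.0
E_Na: 55.0
E_l: -35.0
E_h: -25.0
E_gaba: -90.0
# --- calcium handling (calibrated) ---
beta_ca: 0.045
r: 2.0e-4
z: 2.0
F: 96485.0
P_Ca: 2.56e-6
K_sk: 78.0
ca_leak_frac: 0.1
# --- L-type Ca activation curve (calibrated) ---
ca_vhalf: -42.0
ca_k: 6.0
# --- NMDA voltage dependence (Jahr-Stevens Mg block, [Mg] in mM) ---
Mg: 0.5
m_e: 0.062
# --- Wang-Buzsaki GABA interneuron ---
gaba:
  c_m: 1.0
  gbar_Nag: 22.0
  gbar_Kg: 7.0
  g_lg: 0.1
  E_Na: 55.0
  E_K: -90.0
  E_lg: -51.0
  i_app: 0.0
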
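# Heterogeneous population under correlated OU NMDA drive with tonic
# AMPA/GABA background tone balanced to the control rate.
kind: population
name: fig11
variant: full
seed: 0
duration: 20000
population:
  n_neurons: 50
  condition: tonic_tone
  g_ampa_tone: 0.5
  g_gaba_tone: 1.6
  ou: {mu: 1.5, sigma: 0.5, c: 0.5, tau: 5.0}
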
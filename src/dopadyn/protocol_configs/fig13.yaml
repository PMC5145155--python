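# EtOH condition (scaled Ih + AMPA/GABA tone) vs control under 1 Hz
# sine-modulated correlated NMDA drive.
kind: etoh
name: fig13
variant: full
seed: 0
duration: 20000
population:
  n_neurons: 50
  g_ampa_tone: 0.2
  g_gaba_tone: 0.86
  ou: {mu: 1.5, sigma: 0.5, c: 0.5, tau: 5.0}
options: {gh_etoh: 1.0}
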
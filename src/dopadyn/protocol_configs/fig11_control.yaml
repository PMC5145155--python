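kind: population
name: fig11_control
variant: full
seed: 0
duration: 20000
population:
  n_neurons: 50
  condition: control
  ou: {mu: 1.5, sigma: 0.5, c: 0.5, tau: 5.0}
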
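# Pure Ca-K oscillator (no subthreshold Na): GABA-induced termination.
kind: classify
name: fig3
variant: ca_k_only
seed: 0
param: g_gaba
grid: [0.0, 3.0]
duration: 15000
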
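kind: fi_curve
name: fig5_reduced
variant: reduced
seed: 0
param: g_nmda
grid: {start: 0.5, stop: 12.0, num: 12}
duration: 8000
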
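# Rate map on the tonic NMDA x GABA conductance plane with the balanced-band
# line fit (band anchored at the reference cell's rate +/-50%).
kind: plane_sweep
name: fig2
variant: full
seed: 0
duration: 10000
transient: 2000
x: {param: g_nmda, start: 0.0, stop: 40.0, num: 20}
y: {param: g_gaba, start: 0.0, stop: 6.0, num: 20}
rate_band: [0.7, 2.1]
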
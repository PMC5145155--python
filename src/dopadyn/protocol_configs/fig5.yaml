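# Spike currents barely change the NMDA-driven frequency growth: compare
# with fig5_reduced.
kind: fi_curve
name: fig5
variant: full
seed: 0
param: g_nmda
grid: {start: 0.5, stop: 12.0, num: 12}
duration: 8000
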
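# Tonic NMDA-GABA co-activation at the balanced reference point: ~1.5 Hz.
kind: trace
name: fig2_balance_trace
variant: full
seed: 0
duration: 14000
transient: 2000
drive: {g_nmda: 16.9, g_gaba: 5.0}
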
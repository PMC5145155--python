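# AMPA x GABA plane: firing persists in a much smaller range (no rescue).
kind: plane_sweep
name: fig9
variant: reduced
seed: 0
duration: 10000
transient: 2000
x: {param: g_ampa, start: 0.0, stop: 1.2, num: 16}
y: {param: g_gaba, start: 0.0, stop: 2.0, num: 12}
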
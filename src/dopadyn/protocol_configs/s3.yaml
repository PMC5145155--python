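# AMPA+GABA co-application induces depolarization block in the full model.
kind: plane_sweep
name: s3
variant: full
seed: 0
duration: 8000
x: {param: g_ampa, start: 0.0, stop: 1.2, num: 10}
y: {param: g_gaba, start: 0.0, stop: 2.0, num: 8}
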
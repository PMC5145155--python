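# Hyperpolarizing-current F-I curve of the full model (smooth to zero).
kind: fi_curve
name: s1
variant: full
seed: 0
param: i_app
grid: {start: -10.0, stop: 0.0, num: 25}
direction: falling
duration: 10000
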
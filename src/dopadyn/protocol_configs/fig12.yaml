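# Reward coding by a type I neuron: two-pulse NMDA protocol.
kind: reward
name: fig12
variant: full
seed: 0
reward_values: [0.0, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0]
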
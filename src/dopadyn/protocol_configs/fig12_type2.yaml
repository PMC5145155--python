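# Type II configuration: tonic AMPA compensated by GABA; low rewards are lost.
kind: reward
name: fig12_type2
variant: full
seed: 0
reward_values: [0.0, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0]
options: {type2: true, g_ampa_tone: 0.5, g_gaba_tone: 1.465}
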
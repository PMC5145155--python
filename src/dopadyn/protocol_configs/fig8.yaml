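# Bogdanov-Takens boundary of the combined ohmic synapse (no NMDA).
kind: bt_boundary
name: fig8
variant: reduced
seed: 0
e_grid: [-90.0, -60.0]
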
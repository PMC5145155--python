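# Type I/II boundary shifts down as tonic NMDA grows.
kind: bt_boundary
name: fig10
variant: reduced
seed: 0
drive: {g_nmda: 2.0}
e_grid: [-90.0, -60.0]
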
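# Nullclines of the reduced model near the GABA-induced SNIC.
kind: nullclines
name: fig6
variant: reduced
seed: 0
drive: {g_eff: 0.4, e_eff: -90.0}
options: {v_range: [-80.0, -35.0], n_points: 400}
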
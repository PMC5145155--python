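# Ih-induced bistability: rising/falling applied-current ramps at gh = 7.
kind: hysteresis
name: fig7
variant: reduced
seed: 0
params: {g_h: 7.0}
param: i_app
grid: {start: -12.0, stop: 0.5, num: 50}
duration: 8000
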
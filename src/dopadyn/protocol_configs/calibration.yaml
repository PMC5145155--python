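# Background (no-input) firing of the shipped calibration: 1-5 Hz tonic.
kind: trace
name: calibration
variant: full
seed: 0
duration: 14000
transient: 2000
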
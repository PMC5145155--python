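# Asynchronous synaptic drive: 35 Poisson glutamate trains (~10 Hz) gating
# NMDAR and a 30-neuron Wang-Buzsaki population gating GABAR; firing should
# match the tonic balanced state.
kind: trace
name: fig1
variant: full
seed: 0
duration: 14000
transient: 2000
drive: {g_nmda: 16.9, g_gaba: 5.0}
options: {asynchronous: true}
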
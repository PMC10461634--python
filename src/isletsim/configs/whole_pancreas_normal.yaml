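# Whole-pancreas steady state with basal inflow: ~1 dL of tissue,
# ~1e6 islets, perfused at the organ blood flow rate.
name: whole_pancreas_normal
kind: whole_pancreas
diabetic: false
volume: 100.0
n_islets: 1000000
flow: 1.17
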
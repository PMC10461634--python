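# Type 1 diabetic pancreas: beta-cell secretion and basal insulin are
# zero, so the insulin signal is off and alpha-cells run uninhibited.
name: whole_pancreas_t1d
kind: whole_pancreas
diabetic: true
volume: 100.0
n_islets: 1000000
flow: 1.17
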
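# Total 1-h secretion across glucose levels and islet counts, in both
# static (batch) and flow (perifusion) chambers. The glucagon U-shape
# appears in batch and is flattened by perifusion washout.
name: islet_number_sweep
kind: islet_sweep
modes: [batch, perifusion]
glucose_levels: [1, 4, 7, 10, 15, 20, 30]
islet_counts: [10, 100, 500]
volume: 1.0
flow: 1.0
duration: 60.0
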
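# Human-islet equivalent of a mouse perifusion experiment: a 3 -> 12 mM
# mouse glucose step is rescaled by 0.6 (human/mouse glycemic set
# point) to 1.8 -> 7.2 mM, and run with 5000 islets so the insulin
# level matches the 50-mouse-islet setting.
name: mouse_equivalent_step
kind: glucose_step
species_scale: 0.6
baseline_glucose: 3.0
target_glucose: 12.0
protocol:
  mode: perifusion
  volume: 1.0
  flow: 1.0
  n_islets: 5000
  duration: 60.0
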
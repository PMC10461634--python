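# Perifusion with extra insulin in the inlet (pg/mL): inhibition of
# glucagon secretion across glucose levels.
name: exogenous_insulin
kind: exogenous
hormone: insulin
inlet_levels: [1000.0, 10000.0, 100000.0]
glucose_levels: [1, 4, 7, 10, 15, 20, 30]
n_islets: 15
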
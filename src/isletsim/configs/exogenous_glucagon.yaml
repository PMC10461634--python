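# Perifusion with extra glucagon in the inlet (pg/mL): mild
# potentiation of insulin secretion, strongest at low glucose.
name: exogenous_glucagon
kind: exogenous
hormone: glucagon
inlet_levels: [70.0, 7000.0, 700000.0]
glucose_levels: [1, 4, 7, 10, 15, 20, 30]
n_islets: 15
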
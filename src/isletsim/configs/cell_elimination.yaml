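# Pure cell populations: eliminate alpha-cells (m_G = 0) or beta-cells
# (m_I = 0) and compare steady-state secretion against intact islets.
name: cell_elimination
kind: elimination
which: [alpha, beta]
glucose_levels: [1, 4, 7, 10, 15, 20, 30]
n_islets: 15
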
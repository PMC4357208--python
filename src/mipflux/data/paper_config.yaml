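# Default phenotype window: exponential growth of E. coli on glucose minimal
# medium at mu = 0.2 1/h, with the measured resolution bounds on the cell
# yield, byproduct fluxes, and the admissible ATP yield range.
mu: 0.2                 # specific growth rate, 1/h
yxs_low: 0.39           # g cell / g glucose
yxs_high: 0.45
yxatp_low: 7.0          # g cell / mol ATP
yxatp_high: 10.0
acetate_mode: tight     # tight: r_ACE = acetate_value; loose: acetate_range
acetate_value: 1.0      # mmol/g cell h
acetate_range: [0.8, 1.2]
lactate_flux: 0.0
po_nadh: 2.0            # mol ATP per mol NADH oxidized
po_fadh: 1.0            # mol ATP per mol FADH2 oxidized
glucose_mw: 180.0       # g/mol, for yield <-> flux conversion
transhydrogenase_cap: 0.0   # mmol/g h upper bound on NADH -> NADPH
dna_load_factor: 1.0
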
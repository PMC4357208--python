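# Macromolecular composition of exponentially growing E. coli (g per g dry
# cells) with average monomer masses (g/mmol of residue in the polymer) and
# per-monomer precursor stoichiometries (mol precursor per mol monomer).
# Coefficients are chosen so that the aggregated per-precursor demands
# reproduce the standard published budget for growth on glucose minimal
# medium (e.g. pentose phosphate 0.90, E4P 0.36, oxaloacetate 1.79,
# 2-ketoglutarate 1.08 mmol per g cells). Negative NADH means net production
# by biosynthesis (credited to oxidative phosphorylation).
# DNA precursors per deoxyribonucleotide, at the 50% purine content of duplex
# DNA: purines draw R5P (via PRPP) + 3PG (via serine->glycine); pyrimidines
# draw R5P + OAA (via aspartate); +1 NADPH for ribonucleotide reduction.
macromolecule	mass_fraction	residue_mass	precursors
protein	0.55	0.109	PYR:0.5615;OAA:0.2814;AKG:0.1964;3PG:0.2239;PEP:0.0920;E4P:0.0715;R5P:0.0178;ACCOA:0.0848;NADPH:2.7738;NADH:-0.5946
rna	0.205	0.324	R5P:1.0;3PG:0.5;OAA:0.5
dna	0.031	0.309	R5P:1.0;3PG:0.5;OAA:0.5;NADPH:1.0
lipid	0.091	0.700	ACCOA:17.0;GAP:1.0;NADPH:28.0
other	0.123	0.200	G6P:0.3333;F6P:0.1154;ACCOA:1.8049;AKG:0.1430;PEP:0.0894;R5P:0.1220;NADPH:0.7935
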
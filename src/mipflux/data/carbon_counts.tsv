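# Metabolite registry: carbon counts and whether the species is mass-balanced
# (a row of the stoichiometric matrix). External species (medium glucose,
# excreted byproducts) are unbalanced. NADPH is balanced with zero carbons:
# biosynthetic NADPH demand is a genuine steady-state constraint, while NADH
# and FADH2 are absorbed by respiration and therefore left unbalanced.
metabolite	n_carbons	balanced
GLC	6	0
G6P	6	1
F6P	6	1
P5P	5	1
S7P	7	1
E4P	4	1
GAP	3	1
PEP	3	1
PYR	3	1
ACCOA	2	1
OAA	4	1
AKG	5	1
MAL	4	1
ACE_EX	2	0
LAC_EX	3	0
NADPH	0	1
CO2	1	0
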
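# Central-metabolism network of E. coli at the granularity of the measured
# flux map: glycolysis, hexose monophosphate (HMP) pathway, TCA cycle split at
# alpha-ketoglutarate and malate (so biosynthetic drains and malic enzyme can
# draw on them), PTS glucose uptake, anaplerosis, byproduct excretion.
# Cofactor columns are mol per unit flux: positive = produced.
# NADPH appears both here and as a balanced species (see carbon_counts.tsv);
# NADH/FADH2 are not balanced - net production is respired (P/O-weighted into
# r_ATP). Lumped steps:
#   r_EMP  = GAPDH+PGK+PGM+ENO (GAP -> PEP, +1 NADH, +1 ATP)
#   r_TCA  = CS+ACN+ICDH (NADP-linked; AcCoA+OAA -> AKG, +1 NADPH, +1 CO2)
#   r_AKGD = AKGDH+SCS+SDH+FUM (AKG -> MAL, +1 NADH, +1 GTP=ATP, +1 FADH2)
#   r_ACE  = PTA+ACKA (+1 ATP); r_ANA = PPC (consumes CO2, net-CO2 negative)
#   r_TH   = transhydrogenase NADH -> NADPH, capped by config (default 0)
id	equation	reversible	ATP	NADH	NADPH	FADH2	CO2
r_GLU	GLC + PEP -> G6P + PYR	0	0	0	0	0	0
r_PGI	G6P -> F6P	1	0	0	0	0	0
r_HMP	G6P -> P5P	0	0	0	2	0	1
r_TK1	2 P5P -> S7P + GAP	0	0	0	0	0	0
r_TA	S7P + GAP -> E4P + F6P	0	0	0	0	0	0
r_TK2	P5P + E4P -> F6P + GAP	0	0	0	0	0	0
r_PFK	F6P -> 2 GAP	0	-1	0	0	0	0
r_EMP	GAP -> PEP	1	1	1	0	0	0
r_PYK	PEP -> PYR	0	1	0	0	0	0
r_PDH	PYR -> ACCOA	0	0	1	0	0	1
r_TCA	ACCOA + OAA -> AKG	0	0	0	1	0	1
r_AKGD	AKG -> MAL	0	1	1	0	1	1
r_MDH	MAL -> OAA	1	0	1	0	0	0
r_ME	MAL -> PYR	0	0	0	1	0	1
r_ANA	PEP -> OAA	0	0	0	0	0	-1
r_ACE	ACCOA -> ACE_EX	0	1	0	0	0	0
r_LAC	PYR -> LAC_EX	0	0	-1	0	0	0
r_TH	->	0	0	-1	1	0	0
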
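# The five published extreme flux scenarios (mmol/g cell h; yields g/g and
# g/mol) for the tight-acetate phenotype window at mu = 0.2 1/h.
# Parse notes for the typeset digit runs:
#  - rows 1 and 5 print one token too few for the 11 columns; inserting
#    r_ME = 0 makes the NADPH identity (2 r_HMP + r_TCA + r_ME ~ 3.4) and the
#    anaplerosis identity (r_ANA - r_ME ~ 0.57) hold across all five rows,
#    and row 1 is annotated as the r_ME minimum;
#  - row 2's trailing run is read r_ANA = 1.2, r_CO2 = 4.12 (the alternative
#    1.24 would leave r_CO2 = 0.12, which violates carbon balance).
# 'exact' lists quantities printed as exact constants rather than rounded
# values: zero fluxes, and yields that sit on the configured resolution
# bounds *and* are claimed by the row's own objective annotations (row 5's
# yxs = 0.39 is rounded, not the glucose bound: the glucose-flux maximum is
# annotated on row 4).
# 'cooptimal' lists the row's published objective annotations; r_4/r_5 in
# rows 1 and 3 are unidentifiable (no reaction numbering is published) and
# are omitted.
scenario	objective	cooptimal	yxs	yxatp	r_TCA	r_PYK	r_HMP	r_ME	r_TA	r_TK1	r_TK2	r_ANA	r_CO2	exact
1	MIN r_TCA	MIN r_GLU;MIN r_ME;MAX r_HMP;MAX r_TA;MAX r_TK2	0.45	10	0.60	0.48	1.40	0	0.43	0.43	0.36	0.57	4.64	r_ME;yxs;yxatp
2	MIN r_PYK	-	0.44	10	0.77	0	0.99	0.63	0.29	0.29	0.22	1.2	4.12	r_PYK;yxatp
3	MAX r_ME	MAX r_ANA;MIN r_HMP;MIN r_TA;MIN r_TK2	0.40	7.3	1.6	0	0.32	1.15	0.072	0.072	0	1.7	5.38	r_PYK;r_TK2
4	MAX r_TCA	MAX r_GLU	0.39	7.0	1.7	0.13	0.32	1.1	0.072	0.072	0	1.6	5.72	r_TK2;yxatp
5	MAX r_PYK	MIN r_ANA	0.39	7.0	1.4	0.93	1.00	0	0.30	0.30	0.23	0.57	6.59	r_ME;yxatp
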
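# Methods

## The question the model answers

An *E. coli* host carrying a replication-deregulated, antisense-RNA-selected
plasmid reaches thousands of plasmid copies while its measurable phenotype —
growth rate, cell yield on glucose, byproduct excretion — stays within the
resolution of the measurements.  The model asks how much room those
measurements actually leave: which central-metabolism flux distributions are
*macroscopically indistinguishable* from one another, and how far apart the
extreme ones lie.  That feasible set is the adaptive space the host can move
through (e.g. toward higher ATP production) without a visible phenotype
change.

## Stoichiometric model

The network (`src/mipflux/data/fig1_network.tsv`) covers glucose uptake via
the phosphotransferase system (PEP → pyruvate coupled to import), upper and
lower glycolysis, the oxidative and non-oxidative hexose monophosphate (HMP)
pathway, the TCA cycle split at 2-ketoglutarate and malate, anaplerotic PEP
carboxylation, NADP-linked malic enzyme, and acetate/lactate excretion —
18 reactions over 12 balanced carbon metabolites.  Lumping follows the
granularity at which the fluxes are reported: transketolase appears twice
(TK1 feeding sedoheptulose-7-P, TK2 consuming erythrose-4-P), transaldolase
once; because S7P has no other source or sink, r_TA = r_TK1 always holds.

Cofactors are handled asymmetrically, which is a genuine modelling choice:

- **NADPH is balanced** (a 13th row of `A`): biosynthetic NADPH demand must
  be met by the oxidative HMP branch (2 per G6P), NADP-linked isocitrate
  dehydrogenase, malic enzyme, or a capped transhydrogenase (cap 0 by
  default).  This balance is what couples the HMP/malic-enzyme trade-off.
- **NADH and FADH2 are not balanced**: net production is respired, entering
  the derived gross ATP flux with P/O ratios of 2.0 (NADH) and 1.0 (FADH2).
- **ATP is bounded, not balanced**: gross production (substrate-level +
  oxidative) must fall in the window implied by Y_X/ATP ∈ [7, 10] g/mol,
  i.e. r_ATP ∈ [20, 200/7] mmol/g h at μ = 0.2 h⁻¹.  The gross convention
  matches how Y_X/ATP is defined; polymerization ATP costs are computed and
  reported but not netted out of the bound.

Directionality: uptake, PDH, the TCA steps, anaplerosis, malic enzyme and
byproduct excretion are irreversible; phosphoglucose isomerase, the lumped
lower-glycolysis step, and malate dehydrogenase are reversible.  The
non-oxidative HMP reactions (TK1, TA, TK2) are kept irreversible even
though the enzymes are biochemically reversible: the published extreme
scenarios sit *on* the TK2 = 0 facet, which only exists with the
directional convention of the network figure; with reversible TKs those
scenarios merge and TK2 goes negative.

Carbon is checked reaction-by-reaction at parse time against the bundled
carbon-count table (CO2 from the cofactor column included; anaplerosis
consumes CO2, so it counts negatively in the net CO2 flux).

### Degrees of freedom

With lactate fixed at 0, acetate fixed at 1 mmol/g h and the
transhydrogenase capped at 0, the rank of the balance matrix stacked with
those equality rows leaves **2 degrees of freedom** — the feasible set is a
2-D polygon embedded in 18-D flux space, which is why single flux pairs
fully resolve it.

## Biosynthetic loads

The right-hand side `b` is μ × (composition-weighted precursor demands).
The bundled composition (protein 0.55, RNA 0.205, DNA 0.031, lipid 0.091,
other 0.123 g/g; `data/composition.tsv`) carries per-monomer precursor
stoichiometries whose aggregates reproduce the standard published budget
for glucose-grown *E. coli* (e.g. pentose phosphate 0.90, E4P 0.36, OAA
1.79, 2-ketoglutarate 1.08 mmol per g cells).  Loads are homogeneous of
degree 1 in μ.  3-phosphoglycerate drains are applied at the PEP node
(downstream of the lumped NADH/ATP-producing step), and amino-acid
synthesis carries a net biosynthetic **NADH credit** (~3 mmol/g cells) that
enters the gross ATP flux.

DNA nucleotides draw R5P via PRPP for every base, 3PG (serine → glycine)
for purines, and OAA (aspartate) for pyrimidines — duplex DNA is 50%
purine, so the average dNTP costs 2.0 of the three named precursors.  At
μ = 0.2 h⁻¹ the chromosomal drain is 0.0401 ≈ 0.04 mmol/g h, 1.6% of the
glucose flux; one genome equivalent is ~0.02 mmol/g h (the 3.1% DNA
fraction is ~1.8 genome equivalents at 2.8×10⁻¹³ g dry cell mass), so even
ten extra genome equivalents of plasmid stay under a tenth of glucose
uptake.  `scale_dna_load` multiplies only the DNA-attributable entries.

RNA recycling is modelled as acting on a *turnover* flux (degradation and
repolymerization above net synthesis, default 0 in balanced growth) with a
recycle fraction of 0.8 and an ATP repolymerization surcharge.  Net growth
demand cannot be reduced by recycling — μ × content of pentose phosphate
must be made de novo — and the printed scenario fluxes confirm the full
pentose demand (~0.18 mmol/g h).  Polymerization costs default to 4.3
(protein), 2.4 (RNA) and 1.4 (DNA) ATP per bond — DNA ≈ one third of
protein — plus ~10 ATP per de novo dNTP.

## Calibrating the demand vector against the published scenarios

The published work cites but does not print its load vector, so `b` is
reconstructed from the printed extreme scenarios (1, 2 and 5; the fixture
`data/table1_scenarios.tsv` documents the digit-run parse, including the
r_ME = 0 entries in rows 1 and 5 recovered from the NADPH and anaplerosis
identities).  Plain least squares on the rounded fluxes is too loose: the
scenario-4 corner of the polygon is a *degenerate* vertex (glucose bound,
ATP bound and TK2 = 0 nearly concurrent) and rounding noise splits it into
two clusters.  The calibration therefore distinguishes two kinds of printed
numbers:

- **exact constants** — yield values sitting on the configured resolution
  bounds (0.45 → r_GLU = 2.469, Y_X/ATP = 10 → r_ATP = 20, 7.0 → 200/7)
  and fluxes printed as exactly 0 — are imposed as hard equality
  constraints on the scenario's flux vector, together with A r = b itself;
- **rounded fluxes** (2 significant figures) enter a least-squares
  objective.

Scenario 5's Y_X/S = 0.39 is deliberately *not* treated as the glucose
bound: the glucose-flux maximum is annotated on scenario 4, so 0.39 there
is a rounded interior value.  A weak ridge (weight 10⁻²) pulls `b` toward
the composition-derived prior along directions the printed rows cannot
identify — only the sum of the OAA, AKG and MAL drains, and chain totals
along glycolysis, are pinned; the per-node splits come from the prior and
are reported as free directions.  The fitted vector reproduces the prior to
within a few percent, fits the rounded fluxes with RMS ≈ 0.015 mmol/g h
(the rounding scale), and estimates the NADH credit at 0.62 mmol/g h.
If the residual exceeds 0.15 the routine falls back to the composition
prior outright.

Parameter recovery is verified: from noiseless vertices of a known model
the routine returns `b` to 10⁻⁶.

## Scenario enumeration

Each of the 11 registry fluxes is minimized and maximized (22 LPs,
scipy/HiGHS, fixed constraint ordering, single-threaded — vertex selection
is deterministic).  Optimal vertices agreeing to a relative 10⁻⁶ form one
scenario cluster; each cluster is annotated with every objective whose own
optimum (absolute tolerance 10⁻⁶) is attained there, so ties are annotated
at every corner that reaches them.  Degenerate optima (an optimal face
rather than a point) are detected by re-optimizing a probe direction at the
locked optimum; an optional lexicographic mode returns the total-flux
minimizer on the face as a canonical vertex.

Under the calibrated load the tight-acetate polygon is a pentagon whose
five corners match the published table: the yield-optimal corner (TCA
minimum = biomass-rate maximum, Y_X/S 0.45, Y_X/ATP 10), the
pyruvate-kinase knockout corner, the malic-enzyme maximum (PYK = 0,
TK2 = 0, Y_X/ATP 7.3, with malic enzyme supplying one third of NADPH), the
TCA/glucose maximum, and the PYK maximum (0.93 mmol/g h, about a third of
glucose uptake).  The glucose *upper* bound (2.849) turns out never to
bind: the attainable yield floor is Y_X/S ≈ 0.393, which is what the
printed 0.39 rows reflect.  Loosening acetate to [0.8, 1.2] preserves the
scenario types while widening every flux range (the tight ranges nest
inside the loose ones).

Scaling the DNA-attributable load three-fold on the composition-derived
model leaves the cluster count unchanged.  On the *calibrated* model the
marginal scenario-4 corner sits within printed-rounding distance
(~0.003 in Y_X/S) of the glucose bound, and the same 3× shift pushes it
across, changing the count — an instructive reminder that corner counts of
nearly-degenerate polytopes are not robust observables; the flux ranges
barely move either way.

## 2-D projections

`project_pair` recovers the polygon for any flux pair by a directional LP
sweep (default 128 support directions, deduplicated and hulled); for a
polytope the sweep is exact once the directions include the projection's
facet normals, and doubling directions can only grow the recovered area
(verified as a property, along with equivalence to a brute-force
constraint-intersection vertex oracle on random ≤4-D polytopes).
Degenerate projections (equality-linked pairs) are flagged as segments.
Scenario corners always lie on or inside the polygon, as do convex
combinations of them; the pyruvate-kinase/malic-enzyme pair shows the
expected inverse extreme-point trend.  The published figure caption's
"0.42 ± 0.3" and "8.5 ± 1.5" windows are read as typos for the constraint
windows actually used (± 0.03; 7–10 g/mol), which the defaults follow.

## Synthetic data and the proteome screen

The phenotype generator draws replicate measurements at stated CVs
(defaults: 5% μ, 7% yield, 20% acetate — the acetate spread matching the
loose 0.8–1.2 window) and summarizes them back into a resolution-bounded
constraint set.  The proteome generator emulates duplicate host and
transformant cultures: per-protein log-normal baselines (log-sd 1.0),
multiplicative replicate noise (log-sd 0.1 by default), and a planted set
of fold changes — 40 down in [0.2, 0.5], 29 up in [2.0, 5.0], mirroring a
typical observed 69-protein outcome.  All draws are bit-reproducible under
a fixed seed.

The screen flags a protein when its transformant/host mean-abundance ratio
is < 0.5 or > 2.0 (strict) *and* a two-sample t-test on log abundances
gives p < 0.05.  The default test pools variances: with two replicates per
condition Welch's correction leaves ~1 effective degree of freedom
(critical t up to 12.7) and misses a fifth of genuine two-fold changes at
noise sd 0.1; the pooled test (df = 2) recovers ≥ 0.9 of the planted set
with no false positives at these settings.  No multiple-testing correction
is applied by default, mirroring the published criterion; Benjamini-
Hochberg is available via a flag.  Replicate Pearson correlations on log
abundances exceed 0.98 at the default noise.

What the synthetic data does *not* emulate: peptide-level rollup, isobaric
ratio compression, missing values, or abundance-dependent variance — so
passing screens here demonstrate the rule's behaviour under its own
assumptions, not performance on real spectra.

## Numerical choices and limitations

- LP: HiGHS via scipy, presolve on; infeasibilities are diagnosed by an
  elastic relaxation naming the violated balances/bounds.
- Cluster tolerance 10⁻⁶ (relative), co-optimality 10⁻⁶ (absolute); printed
  comparisons use the printed precision (±1 unit in the last digit).
- The ATP upper bound is carried at full precision 200/7 and displayed as
  28.6.
- Net CO2 is reaction bookkeeping only; CO2 released in biosynthesis
  (~0.2–0.4 mmol/g h) is not modelled, so printed net-CO2 columns deviate
  by up to ~0.4 with inconsistent sign (they are rounding-noisy in the
  source and are not used as anchors).
- Problem sizes: the full model is 18 fluxes × 13 balances; enumeration is
  22 LPs; property tests use 1000 sampled feasible points and 20 random
  ≤4-D oracle polytopes; the synthetic proteome is 1000 proteins × 4
  samples.  The whole suite runs in well under a minute.
- Exponential phase only: no growth-rate-dependent composition shifts, no
  stationary-phase loads, no genome-scale reconstruction, no
  thermodynamic or kinetic constraints.
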
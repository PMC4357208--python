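# mipflux

How much can a cell rearrange its metabolism without anyone noticing?
*E. coli* carrying a replication-deregulated, antisense-RNA-selected plasmid
maintains thousands of plasmid copies — several genome equivalents of extra
DNA — yet grows at the same rate, with the same glucose yield and byproducts,
as the untransformed host.  `mipflux` models the flux space behind such
**macroscopically indistinguishable phenotypes (MIPs)**: all central-carbon
flux distributions consistent with the measured phenotype *within its
experimental resolution*, which is the adaptive room the host has to pay for
plasmid replication (e.g. by making more ATP).

The core is a small stoichiometric model (glycolysis, hexose monophosphate
pathway, TCA cycle, anaplerosis, malic enzyme, byproduct excretion; NADPH
balanced, NADH/FADH2 respired at P/O = 2.0/1.0) constrained by

    A r = b                                (mass balances, biosynthetic loads)
    r_lac = 0,  r_ace = 1 mmol/g h         (measured byproducts; "loose": 0.8-1.2)
    2.469 <= r_glu <= 2.849 mmol/g h       (Y_X/S = 0.42 +/- 0.03 g/g at mu = 0.2 1/h)
    20 <= r_ATP <= 28.6 mmol/g h           (Y_X/ATP in [7, 10] g cell/mol ATP)

which leaves exactly **two degrees of freedom**.  Minimizing and maximizing
every reported flux (FVA-style) harvests the corners of the resulting 2-D
feasible polygon — the extreme flux scenarios.  The demand vector `b` is not
printed in the source study; the package rebuilds it from the cell's
macromolecular composition and *calibrates* it against the published scenario
table by constrained least squares (rounded fluxes fit softly, printed active
bounds held exactly).  A synthetic-proteomics module and the simple
differential screen (fold change < 0.5 or > 2.0 and p < 0.05 on duplicate
samples) close the loop with the study's proteome side.

## Worked example

```python
import mipflux as mf

system, cal, bounds, constraints = mf.calibrated_study()
print(mf.degrees_of_freedom(system))          # 2
table = mf.enumerate_scenarios(system, cal.load, bounds)
print(table.n_clusters)                       # 5
rec = table.cluster_representative(table.cluster_of("MAX r_PYK"))
print(round(rec.optimum, 2), round(rec.yxs, 2), round(rec.yxatp, 1))
shares = mf.nadph_breakdown(
    table.cluster_representative(table.cluster_of("MAX r_ME")), system)
print(round(shares["r_ME"], 2))
```

prints

```
2
5
0.93 0.4 7.0
0.34
```

i.e. the measured phenotype tolerates pyruvate-kinase fluxes from a complete
knockout up to 0.93 mmol/g h (a third of glucose uptake) — that extreme
coming with the low ATP yield (7 g/mol) of a cell burning extra ATP — and at
the malic-enzyme maximum that enzyme alone supplies a third of all NADPH.

The numbered drivers under `analysis/` run the full study and write tables
to `results/`:

```
python analysis/01_calibrate_loads.py     # demand-vector calibration + residuals
python analysis/02_enumerate_scenarios.py # 5 scenarios, FVA ranges, loose acetate
python analysis/03_project_flux_space.py  # 2-D feasible polygons per flux pair
python analysis/04_dna_burden.py          # genome equivalents, 0.04 mmol/g h, 3x test
python analysis/05_proteome_screen.py     # synthetic screen, recall/precision
```

A thin CLI mirrors them (`mipflux scenarios|project|synth|screen`, see
`--help`).  The model, its calibration, and every numerical choice are
documented in `docs/methods.md`.

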
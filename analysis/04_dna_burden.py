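"""Quantify the plasmid DNA burden and test scenario robustness to it.

Computes the genome-equivalents arithmetic for a deregulated high-copy
plasmid, the deoxyribonucleotide precursor drain at the measured growth
rate, and re-enumerates the flux scenarios with the DNA-attributable load
scaled three-fold to check that the scenario structure survives.

Writes results/dna_burden.csv.
"""

from pathlib import Path

import pandas as pd

import mipflux as mf

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

PLASMID_BP = 3.7e3
GENOME_BP = 4.6e6


def main() -> None:
    comp = mf.parse_composition()
    constraints = mf.load_config()
    mu = constraints.mu

    rows = []
    for pcn in (7e3, 15e3):
        ge = mf.genome_equivalents(pcn, PLASMID_BP, GENOME_BP)
        rows.append({"quantity": f"genome equivalents at PCN {pcn:.0f}",
                     "value": ge})
        print(f"PCN {pcn:.0f}: {ge:.1f} genome equivalents of plasmid DNA")

    dna = mf.dna_precursor_load(comp, mu)
    glu = mf.glucose_bounds(constraints.yxs_range, mu)[0]
    rows.append({"quantity": "chromosomal dNTP precursor load (mmol/g h)",
                 "value": dna})
    print(f"dNTP precursor drain at mu={mu}: {dna:.3f} mmol/g h "
          f"({100 * dna / glu:.1f}% of the glucose flux {glu:.2f})")
    from mipflux.loads import chromosomal_genome_equivalents, extra_dna_load

    ge_chrom = chromosomal_genome_equivalents(comp)
    ten_ge = extra_dna_load(comp, mu, 10.0)
    rows.append({"quantity": "load of 10 extra genome equivalents (mmol/g h)",
                 "value": ten_ge})
    print(f"chromosomal DNA is {ge_chrom:.1f} genome equivalents; 10 extra "
          f"would add {ten_ge:.2f} mmol/g h "
          f"({100 * ten_ge / glu:.0f}% of glucose uptake)")

    system = mf.load_default_system()
    bounds = mf.build_bounds(constraints)
    load = mf.compute_load_vector(comp, mu=mu)
    for factor in (1.0, 3.0):
        scaled = mf.scale_dna_load(load, factor)
        table = mf.enumerate_scenarios(
            system, scaled, bounds,
            po_nadh=constraints.po_nadh, po_fadh=constraints.po_fadh)
        rows.append({"quantity": f"scenario clusters at {factor:.0f}x DNA load",
                     "value": table.n_clusters})
        print(f"{factor:.0f}x DNA load: {table.n_clusters} scenario clusters")

    pd.DataFrame(rows).to_csv(OUT / "dna_burden.csv", index=False)
    print(f"wrote {OUT / 'dna_burden.csv'}")


if __name__ == "__main__":
    main()
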
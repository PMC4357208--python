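"""Biosynthetic load vectors: composition x growth rate -> precursor demands.

The right-hand side of the flux balance ``A r = b`` is the drain of central
precursors into macromolecule synthesis at a given specific growth rate mu.
Each macromolecule contributes mu * mass_fraction / residue_mass mmol of
monomers per g cells per hour, multiplied by its per-monomer precursor
stoichiometry.  Demands are homogeneous of degree one in mu.

Beyond carbon precursors the vector carries the NADPH demand (balanced in the
model), a biosynthetic NADH credit (amino-acid synthesis from glucose is a
net NADH producer; the credit enters the gross ATP flux), and the ATP cost of
polymerization (reported, but not netted out of the gross ATP bound, which
follows the Y_X/ATP convention).

Plasmid DNA burden helpers: genome equivalents of plasmid DNA, the combined
R5P + 3PG + OAA drain into deoxyribonucleotides, and scaling of the
DNA-attributable entries to probe increased DNA synthesis.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

#: Precursor labels in composition tables -> balanced species of the bundled
#: network.  3-phosphoglycerate drains are applied at the PEP node (the lumped
#: lower-glycolysis step already produced its NADH and ATP by then), and
#: pentose phosphates are pooled.
PRECURSOR_TO_SPECIES: dict[str, str] = {
    "G6P": "G6P", "F6P": "F6P", "R5P": "P5P", "E4P": "E4P", "GAP": "GAP",
    "3PG": "PEP", "PEP": "PEP", "PYR": "PYR", "ACCOA": "ACCOA",
    "OAA": "OAA", "AKG": "AKG", "MAL": "MAL", "S7P": "S7P",
    "NADPH": "NADPH",
}

DNA_PRECURSORS = ("R5P", "3PG", "OAA")


class CompositionError(ValueError):
    pass


@dataclass(frozen=True)
class Macromolecule:
    name: str
    mass_fraction: float        # g per g cells
    residue_mass: float         # g per mmol monomer in the polymer
    precursors: dict[str, float]  # mol per mol monomer; negative = produced

    def monomer_flux(self, mu: float) -> float:
        """mmol monomers polymerized per g cells per h at growth rate mu."""
        return mu * self.mass_fraction / self.residue_mass


@dataclass(frozen=True)
class Composition:
    macromolecules: tuple[Macromolecule, ...]

    def __post_init__(self) -> None:
        total = 0.0
        for m in self.macromolecules:
            if not (0.0 <= m.mass_fraction <= 1.0):
                raise CompositionError(
                    f"{m.name}: mass fraction {m.mass_fraction} outside [0, 1]"
                )
            if m.residue_mass <= 0:
                raise CompositionError(f"{m.name}: residue mass must be positive")
            total += m.mass_fraction
        if total > 1.0 + 1e-9:
            raise CompositionError(f"mass fractions sum to {total:.3f} > 1")

    def __getitem__(self, name: str) -> Macromolecule:
        for m in self.macromolecules:
            if m.name == name:
                return m
        raise KeyError(name)


@dataclass(frozen=True)
class PolymerizationCosts:
    """ATP per bond by polymer class, plus de novo dNTP synthesis cost.

    DNA polymerization is roughly one third as ATP-expensive per bond as
    protein synthesis, which is part of why very high plasmid copy numbers
    are tolerable.  ``rna_recycle_fraction`` applies to the RNA *turnover*
    flux (degradation/repolymerization above net synthesis): recycled
    nucleotides avoid de novo precursor cost but still pay repolymerization
    ATP.  Turnover is zero by default (balanced exponential growth); it is a
    knob for probing plasmid-driven RNA cycling.
    """

    protein_per_bond: float = 4.3
    rna_per_bond: float = 2.4
    dna_per_bond: float = 1.4
    dntp_de_novo: float = 10.0
    rna_recycle_fraction: float = 0.8
    rna_turnover: float = 0.0   # mmol NMP re-polymerized per g cells per h

    def __post_init__(self) -> None:
        for name in ("protein_per_bond", "rna_per_bond", "dna_per_bond",
                     "dntp_de_novo", "rna_turnover"):
            if getattr(self, name) < 0:
                raise CompositionError(f"{name} must be non-negative")
        if not 0.0 <= self.rna_recycle_fraction <= 1.0:
            raise CompositionError("rna_recycle_fraction must be in [0, 1]")


@dataclass
class LoadVector:
    """Demand vector b at growth rate mu (all fluxes mmol/g cell h).

    ``b`` maps balanced species to biosynthetic drains; ``dna_b`` is the
    DNA-attributable part (included in ``b``), kept separate so the DNA
    burden can be scaled.  ``nadh_production`` is the biosynthetic NADH
    credit; ``atp_demand`` the polymerization ATP cost (with its DNA share).
    """

    mu: float
    b: dict[str, float]
    dna_b: dict[str, float] = field(default_factory=dict)
    nadh_production: float = 0.0
    atp_demand: float = 0.0
    dna_atp_demand: float = 0.0

    def as_array(self, metabolite_order: tuple[str, ...]) -> "np.ndarray":
        import numpy as np

        return np.array([self.b.get(m, 0.0) for m in metabolite_order])


def default_composition_path() -> Path:
    return Path(resources.files("mipflux.data") / "composition.tsv")


def parse_composition(path: str | Path | None = None) -> Composition:
    path = default_composition_path() if path is None else path
    with open(path, newline="") as fh:
        rows = [r for r in fh if not r.lstrip().startswith("#")]
    macros = []
    for row in csv.DictReader(rows, delimiter="\t"):
        precursors: dict[str, float] = {}
        for term in row["precursors"].split(";"):
            term = term.strip()
            if not term:
                continue
            pid, coeff = term.split(":")
            precursors[pid.strip()] = float(coeff)
        macros.append(
            Macromolecule(
                row["macromolecule"].strip(),
                float(row["mass_fraction"]),
                float(row["residue_mass"]),
                precursors,
            )
        )
    return Composition(tuple(macros))


def compute_load_vector(
    composition: Composition,
    costs: PolymerizationCosts | None = None,
    mu: float = 0.2,
    precursor_map: Mapping[str, str] = PRECURSOR_TO_SPECIES,
) -> LoadVector:
    """Demand vector at growth rate mu (mmol/g cell h).

    Precursor demands are mapped onto the network's balanced species;
    negative coefficients (biosynthetic NADH) accumulate into the NADH
    credit rather than the demand vector, which stays non-negative.
    """
    if mu < 0:
        raise CompositionError("mu must be non-negative")
    costs = costs or PolymerizationCosts()
    b: dict[str, float] = {}
    dna_b: dict[str, float] = {}
    nadh_credit = 0.0
    atp = 0.0
    dna_atp = 0.0
    for mac in composition.macromolecules:
        mono = mac.monomer_flux(mu)
        for pid, coeff in mac.precursors.items():
            if pid == "NADH":
                nadh_credit += -coeff * mono
                continue
            species = precursor_map.get(pid, pid)
            amount = coeff * mono
            if amount < 0:
                raise CompositionError(
                    f"{mac.name}: negative demand for {pid} "
                    "(only NADH may be produced)"
                )
            b[species] = b.get(species, 0.0) + amount
            if mac.name == "dna":
                dna_b[species] = dna_b.get(species, 0.0) + amount
        per_bond = {
            "protein": costs.protein_per_bond,
            "rna": costs.rna_per_bond,
            "dna": costs.dna_per_bond,
        }.get(mac.name, 0.0)
        atp += per_bond * mono
        if mac.name == "dna":
            extra = costs.dntp_de_novo * mono
            atp += extra
            dna_atp = (costs.dna_per_bond + costs.dntp_de_novo) * mono
    # RNA turnover: repolymerization ATP always paid; the non-recycled part
    # of the turnover flux also pays de novo precursors (folded into ATP as
    # an aggregate surcharge since its precursor mix matches net RNA).
    atp += costs.rna_turnover * costs.rna_per_bond
    return LoadVector(
        mu=mu, b=b, dna_b=dna_b, nadh_production=nadh_credit,
        atp_demand=atp, dna_atp_demand=dna_atp,
    )


def dna_precursor_load(
    composition: Composition, mu: float,
    precursors: tuple[str, ...] = DNA_PRECURSORS,
) -> float:
    """Combined R5P + 3PG + OAA drain into deoxyribonucleotides (mmol/g h).

    With a 3.1% DNA mass fraction and two precursors per average dNTP
    (purines: R5P + 3PG; pyrimidines: R5P + OAA) this is ~0.04 at mu = 0.2,
    small against a glucose flux of ~2.5.
    """
    dna = composition["dna"]
    if dna.mass_fraction <= 0:
        raise CompositionError("composition has no DNA fraction")
    mono = dna.monomer_flux(mu)
    return mono * sum(dna.precursors.get(p, 0.0) for p in precursors)


#: Mean dry mass of one exponentially growing cell (g) and the mass of one
#: chromosome (bp x mean bp mass / Avogadro); used to express chromosomal
#: DNA content in genome equivalents (~1.8 at moderate growth rates).
CELL_DRY_MASS = 2.8e-13
GENOME_BP = 4.6e6
BP_MASS = 618.0  # g/mol per base pair (2 x 309 g/mol nucleotide residues)
AVOGADRO = 6.02214076e23


def chromosomal_genome_equivalents(
    composition: Composition,
    cell_dry_mass: float = CELL_DRY_MASS,
    genome_bp: float = GENOME_BP,
) -> float:
    """Genome equivalents represented by the cell's own DNA fraction."""
    genome_mass = genome_bp * BP_MASS / AVOGADRO
    return composition["dna"].mass_fraction * cell_dry_mass / genome_mass


def extra_dna_load(
    composition: Composition,
    mu: float,
    n_genome_equivalents: float,
    cell_dry_mass: float = CELL_DRY_MASS,
    genome_bp: float = GENOME_BP,
) -> float:
    """Precursor drain (mmol/g h) of extra DNA in genome equivalents.

    Ten genome equivalents of plasmid DNA at mu = 0.2 cost under 10% of the
    glucose flux — part of why enormous copy numbers barely touch growth.
    """
    per_ge = dna_precursor_load(composition, mu) / chromosomal_genome_equivalents(
        composition, cell_dry_mass, genome_bp
    )
    return n_genome_equivalents * per_ge


def genome_equivalents(pcn: float, plasmid_bp: float, genome_bp: float) -> float:
    """Plasmid DNA content expressed in chromosome equivalents."""
    if plasmid_bp <= 0 or genome_bp <= 0:
        raise CompositionError("plasmid and genome sizes must be positive")
    if pcn < 0:
        raise CompositionError("copy number must be non-negative")
    return pcn * plasmid_bp / genome_bp


def scale_dna_load(load: LoadVector, factor: float) -> LoadVector:
    """Multiply only the DNA-attributable entries (precursors and dNTP ATP).

    Composing two scalings multiplies the factors on the DNA part; all other
    demands are untouched.
    """
    if factor < 0:
        raise CompositionError("factor must be non-negative")
    b = dict(load.b)
    dna_b = {}
    for species, amount in load.dna_b.items():
        b[species] = b.get(species, 0.0) + (factor - 1.0) * amount
        dna_b[species] = factor * amount
    return replace(
        load,
        b=b,
        dna_b=dna_b,
        atp_demand=load.atp_demand + (factor - 1.0) * load.dna_atp_demand,
        dna_atp_demand=factor * load.dna_atp_demand,
    )
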
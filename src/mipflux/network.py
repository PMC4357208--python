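"""Stoichiometric model of E. coli central metabolism.

The network is read from a delimited reaction table (see
``data/fig1_network.tsv``) covering glycolysis, the hexose monophosphate
pathway, the TCA cycle, anaplerosis, malic enzyme and byproduct excretion,
lumped to the granularity at which fluxes are usually reported for this
organism.  Cofactor turnover (ATP, NADH, NADPH, FADH2, CO2) is carried per
reaction alongside the carbon stoichiometry.  Internal metabolites are
mass-balanced; NADPH is additionally balanced (biosynthetic redox demand is a
real steady-state constraint), while NADH and FADH2 are left free and their
net production is assumed respired, entering the derived ATP flux with the
configured P/O ratios.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

COFACTORS = ("ATP", "NADH", "NADPH", "FADH2", "CO2")

#: Reactions whose fluxes the study reports (the named arrows of the network
#: figure); enumeration and the scenario table run over these.
REGISTRY_FLUXES = (
    "r_GLU", "r_HMP", "r_TA", "r_TK1", "r_TK2", "r_TCA",
    "r_PYK", "r_ME", "r_ANA", "r_LAC", "r_ACE",
)


class NetworkError(ValueError):
    """Raised for malformed or inconsistent network definitions."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    n_carbons: int
    balanced: bool
    name: str = ""


@dataclass
class Reaction:
    """A (possibly lumped) reaction.

    ``stoichiometry`` maps metabolite id to a signed molar coefficient;
    ``cofactor_yields`` holds signed cofactor production per unit flux.
    """

    id: str
    stoichiometry: dict[str, float]
    reversible: bool
    cofactor_yields: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        nonzero = any(v != 0 for v in self.stoichiometry.values())
        nonzero = nonzero or any(v != 0 for v in self.cofactor_yields.values())
        if not nonzero:
            raise NetworkError(f"reaction {self.id!r} has no nonzero coefficient")


@dataclass
class StoichiometricSystem:
    """Assembled balance matrix ``A`` (balanced species x reactions).

    Rows follow ``metabolite_order`` (balanced species, sorted), columns
    follow ``flux_order`` (reaction declaration order), so the matrix is
    reproducible from the reaction list regardless of dict ordering.
    """

    A: np.ndarray
    flux_order: tuple[str, ...]
    metabolite_order: tuple[str, ...]
    carbon_counts: dict[str, int]
    reactions: dict[str, Reaction]
    reversible: frozenset[str]

    @property
    def n_fluxes(self) -> int:
        return len(self.flux_order)

    def flux_index(self, flux_id: str) -> int:
        try:
            return self.flux_order.index(flux_id)
        except ValueError:
            raise KeyError(f"unknown flux {flux_id!r}") from None

    def cofactor_row(self, cofactor: str) -> np.ndarray:
        """Per-unit-flux production of one cofactor, as a vector over fluxes."""
        if cofactor not in COFACTORS:
            raise KeyError(f"unknown cofactor {cofactor!r}")
        row = np.zeros(self.n_fluxes)
        for j, fid in enumerate(self.flux_order):
            row[j] = self.reactions[fid].cofactor_yields.get(cofactor, 0.0)
        return row

    def atp_row(self, po_nadh: float = 2.0, po_fadh: float = 1.0) -> np.ndarray:
        """Coefficients of gross ATP production as a linear form in fluxes.

        Substrate-level ATP plus P/O-weighted oxidation of net NADH and
        FADH2.  NADPH is excluded: it is balanced against biosynthesis, not
        respired.
        """
        return (
            self.cofactor_row("ATP")
            + po_nadh * self.cofactor_row("NADH")
            + po_fadh * self.cofactor_row("FADH2")
        )


@dataclass
class FluxVector:
    """A complete flux assignment over a system's reactions (mmol/g cell h)."""

    values: dict[str, float]

    def __getitem__(self, flux_id: str) -> float:
        return self.values[flux_id]

    def as_array(self, system: StoichiometricSystem) -> np.ndarray:
        missing = [f for f in system.flux_order if f not in self.values]
        if missing:
            raise KeyError(f"flux vector missing entries for {missing}")
        return np.array([self.values[f] for f in system.flux_order])


def _data_path(name: str) -> Path:
    return Path(resources.files("mipflux.data") / name)


def default_network_path() -> Path:
    return _data_path("fig1_network.tsv")


def default_carbon_path() -> Path:
    return _data_path("carbon_counts.tsv")


def _read_table(path: str | Path) -> list[dict[str, str]]:
    with open(path, newline="") as fh:
        rows = [r for r in fh if not r.lstrip().startswith("#")]
    return list(csv.DictReader(rows, delimiter="\t"))


def parse_metabolites(path: str | Path | None = None) -> list[Metabolite]:
    path = default_carbon_path() if path is None else path
    mets: list[Metabolite] = []
    seen: set[str] = set()
    for row in _read_table(path):
        mid = row["metabolite"].strip()
        if mid in seen:
            raise NetworkError(f"duplicate metabolite id {mid!r}")
        seen.add(mid)
        mets.append(
            Metabolite(mid, int(row["n_carbons"]), bool(int(row["balanced"])))
        )
    return mets


def _parse_equation(eq: str, line_no: int) -> dict[str, float]:
    """Parse ``"A + 2 B -> C"`` into signed coefficients."""
    stoich: dict[str, float] = {}
    if "->" not in eq:
        raise NetworkError(f"line {line_no}: equation {eq!r} lacks '->'")
    lhs, rhs = eq.split("->")
    for side, sign in ((lhs, -1.0), (rhs, +1.0)):
        for term in side.split("+"):
            term = term.strip()
            if not term:
                continue
            parts = term.split()
            if len(parts) == 2:
                coeff, met = float(parts[0]), parts[1]
            elif len(parts) == 1:
                coeff, met = 1.0, parts[0]
            else:
                raise NetworkError(f"line {line_no}: cannot parse term {term!r}")
            stoich[met] = stoich.get(met, 0.0) + sign * coeff
    return stoich


def parse_network(
    path: str | Path | None = None,
    metabolites: Sequence[Metabolite] | None = None,
) -> tuple[list[Reaction], list[Metabolite]]:
    """Read and validate a reaction table.

    Every metabolite referenced must be declared in the metabolite registry,
    and every reaction must balance carbon (stoichiometric carbon plus the
    CO2 cofactor column).
    """
    path = default_network_path() if path is None else path
    metabolites = list(metabolites) if metabolites is not None else parse_metabolites()
    met_ids = {m.id for m in metabolites}
    carbons = {m.id: m.n_carbons for m in metabolites}

    reactions: list[Reaction] = []
    seen: set[str] = set()
    for line_no, row in enumerate(_read_table(path), start=2):
        rid = row["id"].strip()
        if rid in seen:
            raise NetworkError(f"line {line_no}: duplicate reaction id {rid!r}")
        seen.add(rid)
        stoich = _parse_equation(row["equation"], line_no)
        for met in stoich:
            if met not in met_ids:
                raise NetworkError(
                    f"line {line_no}: reaction {rid!r} references unknown "
                    f"metabolite {met!r}"
                )
        yields = {c: float(row.get(c, 0) or 0) for c in COFACTORS}
        rxn = Reaction(rid, stoich, bool(int(row["reversible"])), yields)
        carbon = sum(c * carbons[m] for m, c in stoich.items())
        carbon += yields["CO2"] * carbons.get("CO2", 1)
        if abs(carbon) > 1e-9:
            raise NetworkError(
                f"reaction {rid!r} does not balance carbon (residual {carbon:g})"
            )
        reactions.append(rxn)
    if not reactions:
        raise NetworkError("no reactions")
    return reactions, metabolites


def assemble_system(
    reactions: Sequence[Reaction], metabolites: Sequence[Metabolite]
) -> StoichiometricSystem:
    """Build the balance matrix over balanced species.

    Balanced cofactor species (here NADPH) get their row from the cofactor
    yield columns; all other rows come from the reaction equations.
    """
    if not reactions:
        raise NetworkError("no reactions")
    balanced = sorted(m.id for m in metabolites if m.balanced)
    flux_order = tuple(r.id for r in reactions)
    A = np.zeros((len(balanced), len(flux_order)))
    for j, rxn in enumerate(reactions):
        for met, coeff in rxn.stoichiometry.items():
            if met in balanced:
                A[balanced.index(met), j] += coeff
        for cof, coeff in rxn.cofactor_yields.items():
            if cof in balanced:
                A[balanced.index(cof), j] += coeff
    return StoichiometricSystem(
        A=A,
        flux_order=flux_order,
        metabolite_order=tuple(balanced),
        carbon_counts={m.id: m.n_carbons for m in metabolites},
        reactions={r.id: r for r in reactions},
        reversible=frozenset(r.id for r in reactions if r.reversible),
    )


def load_default_system() -> StoichiometricSystem:
    reactions, metabolites = parse_network()
    return assemble_system(reactions, metabolites)


def degrees_of_freedom(
    system: StoichiometricSystem,
    equality_fluxes: Iterable[str] = ("r_LAC", "r_ACE", "r_TH"),
) -> int:
    """Number of free flux directions after mass balances and equalities.

    Computed as (number of fluxes) minus the rank of the balance matrix
    stacked with a unit row per flux fixed to a measured value.  With lactate
    and acetate fixed (and transhydrogenase capped off) the bundled network
    leaves two degrees of freedom.
    """
    rows = [system.A]
    for fid in equality_fluxes:
        e = np.zeros((1, system.n_fluxes))
        e[0, system.flux_index(fid)] = 1.0
        rows.append(e)
    stacked = np.vstack(rows)
    return system.n_fluxes - int(np.linalg.matrix_rank(stacked))


@dataclass(frozen=True)
class DerivedFluxes:
    """Cofactor totals implied by a flux vector (mmol/g cell h)."""

    r_co2: float
    r_atp: float
    nadh: float
    nadph: float
    fadh2: float
    atp_substrate_level: float


def derived_fluxes(
    flux_vector: FluxVector | Mapping[str, float],
    system: StoichiometricSystem,
    po_nadh: float = 2.0,
    po_fadh: float = 1.0,
    nadh_credit: float = 0.0,
) -> DerivedFluxes:
    """Net CO2 and gross ATP production for a flux vector.

    ``r_atp`` is gross production: substrate-level ATP plus P/O-weighted
    oxidation of net NADH (including any biosynthetic NADH credit carried by
    the load vector) and FADH2.  CO2 consumed by anaplerosis counts
    negatively in ``r_co2``.
    """
    if not isinstance(flux_vector, FluxVector):
        flux_vector = FluxVector(dict(flux_vector))
    r = flux_vector.as_array(system)
    slp = float(system.cofactor_row("ATP") @ r)
    nadh = float(system.cofactor_row("NADH") @ r) + nadh_credit
    nadph = float(system.cofactor_row("NADPH") @ r)
    fadh2 = float(system.cofactor_row("FADH2") @ r)
    co2 = float(system.cofactor_row("CO2") @ r)
    atp = slp + po_nadh * nadh + po_fadh * fadh2
    return DerivedFluxes(co2, atp, nadh, nadph, fadh2, slp)


def carbon_closure(
    flux_vector: FluxVector | Mapping[str, float],
    system: StoichiometricSystem,
    demands: Mapping[str, float],
) -> float:
    """Carbon-balance residual: uptake minus (biomass + byproducts + CO2).

    ``demands`` maps balanced metabolite ids to biosynthetic drain fluxes.
    Zero (to numerical tolerance) for any solution of ``A r = b``.
    """
    if not isinstance(flux_vector, FluxVector):
        flux_vector = FluxVector(dict(flux_vector))
    r = flux_vector.as_array(system)
    cc = system.carbon_counts
    uptake = 0.0
    excreted = 0.0
    for j, fid in enumerate(system.flux_order):
        for met, coeff in system.reactions[fid].stoichiometry.items():
            if met in system.metabolite_order:
                continue
            flow = coeff * r[j] * cc[met]
            if flow < 0:
                uptake += -flow
            else:
                excreted += flow
    co2 = float(system.cofactor_row("CO2") @ r)
    biomass = sum(cc[m] * v for m, v in demands.items() if m in cc)
    return uptake - (excreted + co2 + biomass)
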
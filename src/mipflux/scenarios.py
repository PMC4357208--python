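"""Extreme flux scenarios behind one measured phenotype.

Each registry flux is minimized and maximized by linear programming over the
measurement-constrained flux polytope; the optimal vertices are clustered
into distinct scenarios and each cluster is annotated with every objective
that attains its optimum there ("co-optimal" classification).  Because the
constrained system retains two degrees of freedom, the feasible set is a
two-dimensional polygon embedded in flux space and the enumeration harvests
its corners.

Also here: the calibration of the demand vector b against published extreme
scenarios.  Printed scenario fluxes are rounded to two significant figures,
but the values of *active* measurement bounds (yields sitting on their
resolution limits, fluxes printed as exactly zero) are exact constants; the
calibration therefore solves an equality-constrained least-squares problem
in which each printed scenario lies exactly on the model plane A r = b and
on its printed active bounds, while the rounded flux values are fit softly.
A weak ridge toward the composition-derived load resolves the directions of
b the printed data cannot identify (e.g. only the sum of the OAA, AKG and
MAL drains is determined).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

from .constraints import (
    BoundSet,
    PhenotypeConstraints,
    build_bounds,
    yxatp_of_atp_flux,
    yxs_of_glucose_flux,
)
from .loads import LoadVector
from .network import (
    REGISTRY_FLUXES,
    FluxVector,
    StoichiometricSystem,
    derived_fluxes,
)

logger = logging.getLogger(__name__)

#: Vertex identity tolerance (relative, on flux vectors) and co-optimality
#: tolerance (absolute, on objective values).  Printed tables round to two
#: significant figures; internal tolerances are far tighter.
CLUSTER_TOL = 1e-6
CO_OPTIMAL_TOL = 1e-6


class ScenarioError(RuntimeError):
    pass


class InfeasibleError(ScenarioError):
    """LP infeasible; carries a diagnosis of conflicting constraints."""


@dataclass(frozen=True)
class ObjectiveSpec:
    flux_id: str
    sense: str  # "minimize" | "maximize"

    def __post_init__(self) -> None:
        if self.sense not in ("minimize", "maximize"):
            raise ValueError(f"bad sense {self.sense!r}")

    @property
    def label(self) -> str:
        return ("MIN " if self.sense == "minimize" else "MAX ") + self.flux_id


@dataclass
class ScenarioRecord:
    objective: ObjectiveSpec
    fluxes: FluxVector
    optimum: float
    yxs: float
    yxatp: float
    r_atp: float
    r_co2: float
    status: str = "optimal"
    degenerate: bool = False
    co_optimal: list[ObjectiveSpec] = field(default_factory=list)


@dataclass
class ScenarioTable:
    records: list[ScenarioRecord]
    clusters: list[list[int]] = field(default_factory=list)  # record indices

    def cluster_of(self, label: str) -> int:
        for ci, members in enumerate(self.clusters):
            if any(self.records[i].objective.label == label for i in members):
                return ci
        raise KeyError(label)

    def cluster_representative(self, ci: int) -> ScenarioRecord:
        return self.records[self.clusters[ci][0]]

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


class _LP:
    """Shared LP machinery: equalities A r = b, ATP window, flux bounds."""

    def __init__(
        self,
        system: StoichiometricSystem,
        load: LoadVector,
        bounds: BoundSet,
        po_nadh: float = 2.0,
        po_fadh: float = 1.0,
    ):
        self.system = system
        self.load = load
        self.bounds = bounds
        self.po = (po_nadh, po_fadh)
        self.A_eq = system.A
        self.b_eq = load.as_array(system.metabolite_order)
        self.atp_row = system.atp_row(po_nadh, po_fadh)
        self.atp_offset = po_nadh * load.nadh_production
        lo_atp, hi_atp = bounds["r_ATP"] if "r_ATP" in bounds else (-np.inf, np.inf)
        rows, rhs = [], []
        if np.isfinite(hi_atp):
            rows.append(self.atp_row)
            rhs.append(hi_atp - self.atp_offset)
        if np.isfinite(lo_atp):
            rows.append(-self.atp_row)
            rhs.append(-(lo_atp - self.atp_offset))
        self.A_ub = np.vstack(rows) if rows else None
        self.b_ub = np.array(rhs) if rows else None
        self.var_bounds = []
        for fid in system.flux_order:
            lo = -np.inf if fid in system.reversible else 0.0
            hi = np.inf
            if fid in bounds and fid != "r_ATP":
                blo, bhi = bounds[fid]
                lo, hi = max(lo, blo), min(hi, bhi)
            self.var_bounds.append((lo, hi))

    def solve(self, c: np.ndarray) -> np.ndarray:
        res = linprog(
            c,
            A_ub=self.A_ub,
            b_ub=self.b_ub,
            A_eq=self.A_eq,
            b_eq=self.b_eq,
            bounds=self.var_bounds,
            method="highs",
            options={"presolve": True},
        )
        if res.status == 2:
            raise InfeasibleError(self._diagnose())
        if res.status == 3:
            raise ScenarioError("LP unbounded along the objective direction")
        if res.status != 0:
            raise ScenarioError(f"solver failure: {res.message}")
        return res.x

    def _diagnose(self) -> str:
        """Name the constraint groups that conflict, via elastic relaxation."""
        n = self.system.n_fluxes
        n_eq = self.A_eq.shape[0]
        n_ub = 0 if self.A_ub is None else self.A_ub.shape[0]
        # elastic variables on each equality row and each ATP inequality
        A_eq = np.hstack([self.A_eq, np.eye(n_eq), -np.eye(n_eq),
                          np.zeros((n_eq, n_ub))])
        A_ub = None
        if n_ub:
            A_ub = np.hstack([self.A_ub, np.zeros((n_ub, 2 * n_eq)),
                              -np.eye(n_ub)])
        c = np.concatenate([np.zeros(n), np.ones(2 * n_eq + n_ub)])
        bounds = self.var_bounds + [(0, None)] * (2 * n_eq + n_ub)
        res = linprog(c, A_ub=A_ub, b_ub=self.b_ub, A_eq=A_eq, b_eq=self.b_eq,
                      bounds=bounds, method="highs")
        if res.status != 0:
            return "infeasible (diagnosis LP failed)"
        slack = res.x[n:]
        parts = []
        for i, m in enumerate(self.system.metabolite_order):
            v = slack[i] + slack[n_eq + i]
            if v > 1e-6:
                parts.append(f"balance {m} (violation {v:.3g})")
        atp_names = ("ATP upper bound", "ATP lower bound")
        for k in range(n_ub):
            if slack[2 * n_eq + k] > 1e-6:
                parts.append(
                    f"{atp_names[k]} (violation {slack[2 * n_eq + k]:.3g})")
        return "infeasible; binding conflicts: " + (", ".join(parts) or "flux bounds")


def _record_from_solution(
    lp: _LP, objective: ObjectiveSpec, x: np.ndarray
) -> ScenarioRecord:
    system = lp.system
    fv = FluxVector(dict(zip(system.flux_order, map(float, x))))
    der = derived_fluxes(fv, system, *lp.po, nadh_credit=lp.load.nadh_production)
    mu = lp.load.mu
    yxs = (yxs_of_glucose_flux(fv["r_GLU"], mu)
           if "r_GLU" in fv.values and fv["r_GLU"] > 0 else float("nan"))
    yxatp = yxatp_of_atp_flux(der.r_atp, mu) if der.r_atp > 0 else float("nan")
    return ScenarioRecord(
        objective=objective,
        fluxes=fv,
        optimum=float(x[system.flux_index(objective.flux_id)]),
        yxs=yxs,
        yxatp=yxatp,
        r_atp=der.r_atp,
        r_co2=der.r_co2,
    )


def solve_lp(
    system: StoichiometricSystem,
    load: LoadVector,
    bounds: BoundSet,
    objective: ObjectiveSpec,
    po_nadh: float = 2.0,
    po_fadh: float = 1.0,
    detect_degenerate: bool = True,
    lexicographic: bool = False,
) -> ScenarioRecord:
    """Optimize one flux over the constrained polytope.

    Returns the solver's optimal vertex.  If the optimal face is not a
    point, the record is flagged degenerate (probed by re-optimizing a fixed
    secondary direction at the locked optimum); with ``lexicographic`` the
    total-flux minimizer on the optimal face is returned instead, making the
    reported vertex canonical.
    """
    lp = _LP(system, load, bounds, po_nadh, po_fadh)
    n = system.n_fluxes
    c = np.zeros(n)
    j = system.flux_index(objective.flux_id)
    c[j] = 1.0 if objective.sense == "minimize" else -1.0
    x = lp.solve(c)
    logger.info("%s: optimum %.6g", objective.label, x[j])
    rec = _record_from_solution(lp, objective, x)
    if detect_degenerate or lexicographic:
        # lock the objective, probe/minimize total flux on the optimal face
        lp2 = _LP(system, load, bounds, po_nadh, po_fadh)
        lock = np.zeros(n)
        lock[j] = 1.0
        lp2.A_eq = np.vstack([lp.A_eq, lock])
        lp2.b_eq = np.append(lp.b_eq, x[j])
        probe = np.ones(n)
        x_min = lp2.solve(probe)
        if lexicographic:
            rec = _record_from_solution(lp, objective, x_min)
            rec.optimum = float(x[j])
        x_max = lp2.solve(-probe)
        if abs(probe @ x_max - probe @ x_min) > 1e-7 * max(1.0, abs(probe @ x_min)):
            rec.degenerate = True
    return rec


def enumerate_scenarios(
    system: StoichiometricSystem,
    load: LoadVector,
    bounds: BoundSet,
    flux_ids: Sequence[str] = REGISTRY_FLUXES,
    po_nadh: float = 2.0,
    po_fadh: float = 1.0,
    cluster_tol: float = CLUSTER_TOL,
) -> ScenarioTable:
    """Min/max every registry flux and cluster the optimal vertices.

    2 x len(flux_ids) LPs; deterministic (fixed constraint ordering,
    single-threaded dual simplex).  Records whose flux vectors agree within
    ``cluster_tol`` (relative) form one scenario cluster.
    """
    records: list[ScenarioRecord] = []
    for fid in flux_ids:
        for sense in ("minimize", "maximize"):
            records.append(
                solve_lp(system, load, bounds, ObjectiveSpec(fid, sense),
                         po_nadh, po_fadh, detect_degenerate=False)
            )
    table = ScenarioTable(records)
    vecs = [r.fluxes.as_array(system) for r in records]
    scale = max(1.0, max(float(np.max(np.abs(v))) for v in vecs))
    for i, v in enumerate(vecs):
        for members in table.clusters:
            if np.max(np.abs(v - vecs[members[0]])) <= cluster_tol * scale:
                members.append(i)
                break
        else:
            table.clusters.append([i])
    return classify_co_optimal(table, system)


def classify_co_optimal(
    table: ScenarioTable,
    system: StoichiometricSystem,
    tol: float = CO_OPTIMAL_TOL,
) -> ScenarioTable:
    """Annotate each cluster with every objective optimal at its vertex.

    An objective is co-optimal at a cluster if the cluster vertex attains
    that objective's optimum within ``tol`` — so ties (the same extreme
    value reached at several corners) are annotated at every corner that
    attains them.
    """
    optima = {r.objective.label: r.optimum for r in table.records}
    for members in table.clusters:
        rep = table.records[members[0]]
        co: list[ObjectiveSpec] = []
        for rec in table.records:
            val = rep.fluxes[rec.objective.flux_id]
            if abs(val - optima[rec.objective.label]) <= tol:
                co.append(rec.objective)
        for i in members:
            table.records[i].co_optimal = co
    return table


def biomass_max_equivalence(
    system: StoichiometricSystem,
    load: LoadVector,
    bounds: BoundSet,
    table: ScenarioTable | None = None,
    **lp_kw,
) -> tuple[ScenarioRecord, bool]:
    """Maximize biomass production rate and test identity with MIN r_TCA.

    At fixed growth rate, maximizing Y_X/S * mu is minimizing glucose
    uptake.  Returns the record and whether it lands in the same cluster as
    the TCA minimum (true for the calibrated model, mirroring the
    observation that the TCA-minimal scenario is also the biomass-yield
    optimum).
    """
    rec = solve_lp(system, load, bounds,
                   ObjectiveSpec("r_GLU", "minimize"), **lp_kw)
    if table is None:
        table = enumerate_scenarios(system, load, bounds)
    rep = table.cluster_representative(table.cluster_of("MIN r_TCA"))
    same = bool(
        np.max(np.abs(rec.fluxes.as_array(system) - rep.fluxes.as_array(system)))
        <= CLUSTER_TOL * 10
    )
    return rec, same


def nadph_breakdown(
    record: ScenarioRecord | FluxVector | Mapping[str, float],
    system: StoichiometricSystem,
) -> dict[str, float]:
    """Fractional NADPH supply by source.

    Sources are the reactions with positive NADPH yield: the oxidative HMP
    branch (2 per glucose-6-phosphate diverted), NADP-linked isocitrate
    dehydrogenase (in the lumped TCA step), malic enzyme, and
    transhydrogenase.  Fractions sum to one.
    """
    fv = record.fluxes if isinstance(record, ScenarioRecord) else record
    if not isinstance(fv, FluxVector):
        fv = FluxVector(dict(fv))
    contributions: dict[str, float] = {}
    for fid in system.flux_order:
        y = system.reactions[fid].cofactor_yields.get("NADPH", 0.0)
        if y > 0:
            contributions[fid] = y * max(fv[fid], 0.0)
    total = sum(contributions.values())
    if total <= 0:
        raise ScenarioError("flux vector produces no NADPH")
    return {fid: v / total for fid, v in contributions.items()}


# ---------------------------------------------------------------------------
# Calibration of the demand vector against printed scenarios


@dataclass(frozen=True)
class PrintedScenario:
    """One published extreme scenario: rounded fluxes plus exact actives.

    ``fluxes`` are the printed values (registry fluxes; yields are converted
    to r_GLU / r_ATP before fitting).  ``exact`` names quantities printed as
    exact constants: zero fluxes and yields sitting on the measurement
    bounds ("r_GLU", "r_ATP" select the yield-derived quantities).
    """

    name: str
    objective: str
    fluxes: dict[str, float]
    exact: tuple[str, ...] = ()
    cooptimal: tuple[str, ...] = ()
    yxs: float | None = None
    yxatp: float | None = None
    r_co2: float | None = None


@dataclass
class CalibrationResult:
    load: LoadVector
    residual_rms: float
    residual_max: float
    nadh_production: float
    free_directions: list[str]
    fitted_points: dict[str, FluxVector]
    used_fallback: bool = False


def default_scenario_path() -> Path:
    return Path(resources.files("mipflux.data") / "table1_scenarios.tsv")


def load_printed_scenarios(
    path: str | Path | None = None,
    constraints: PhenotypeConstraints | None = None,
) -> list[PrintedScenario]:
    """Read the published scenario table fixture.

    Yields are converted to fluxes with the configured growth rate and
    glucose molar mass; 'exact' markers yxs/yxatp become exact r_GLU/r_ATP
    values at the corresponding measurement bound.
    """
    path = default_scenario_path() if path is None else path
    constraints = constraints or PhenotypeConstraints()
    mu, mw = constraints.mu, constraints.glucose_mw / 1000.0
    out: list[PrintedScenario] = []
    with open(path, newline="") as fh:
        rows = [r for r in fh if not r.lstrip().startswith("#")]
    for row in csv.DictReader(rows, delimiter="\t"):
        fluxes: dict[str, float] = {}
        for fid in ("r_TCA", "r_PYK", "r_HMP", "r_ME", "r_TA", "r_TK1",
                    "r_TK2", "r_ANA"):
            fluxes[fid] = float(row[fid])
        yxs, yxatp = float(row["yxs"]), float(row["yxatp"])
        fluxes["r_GLU"] = mu / (yxs * mw)
        fluxes["r_ATP"] = 1000.0 * mu / yxatp
        exact = []
        for token in row["exact"].split(";"):
            token = token.strip()
            if not token or token == "-":
                continue
            if token == "yxs":
                exact.append("r_GLU")
            elif token == "yxatp":
                exact.append("r_ATP")
            else:
                exact.append(token)
        coopt = tuple(
            t.strip() for t in row["cooptimal"].split(";")
            if t.strip() and t.strip() != "-"
        )
        out.append(
            PrintedScenario(
                name=row["scenario"].strip(),
                objective=row["objective"].strip(),
                fluxes=fluxes,
                exact=tuple(exact),
                cooptimal=coopt,
                yxs=yxs,
                yxatp=yxatp,
                r_co2=float(row["r_CO2"]),
            )
        )
    return out


def calibrate_loads(
    system: StoichiometricSystem,
    bounds: BoundSet,
    printed_scenarios: Sequence[PrintedScenario],
    prior: LoadVector,
    po_nadh: float = 2.0,
    po_fadh: float = 1.0,
    ridge: float = 1e-2,
    residual_threshold: float = 0.15,
    mu: float = 0.2,
) -> CalibrationResult:
    """Reconstruct the demand vector b from published extreme scenarios.

    Decision variables are one full flux vector per printed scenario, the
    demand vector b (non-negative), and the biosynthetic NADH credit.  Hard
    equality constraints: A r_k = b; the gross-ATP identity at each
    scenario's printed ATP value when marked exact; every flux marked exact
    (zeros, yield-bound fluxes); and the fixed byproduct fluxes.  The
    rounded printed fluxes enter a least-squares objective, with a weak
    ridge (weight ``ridge``) pulling b and the credit toward the
    composition-derived prior on unidentified directions.

    If fewer than two scenarios are supplied, or the soft residual RMS
    exceeds ``residual_threshold`` (printed rounding noise is ~0.005-0.05),
    the composition-derived prior is returned unchanged (fallback).
    Directions of b with negligible sensitivity in the fit are reported as
    free (they are pinned by the prior alone).
    """
    if len(printed_scenarios) < 2:
        raise ScenarioError("need at least two printed scenarios to calibrate")
    n = system.n_fluxes
    mets = system.metabolite_order
    nm = len(mets)
    nS = len(printed_scenarios)
    atp_row = system.atp_row(po_nadh, po_fadh)
    nv = nS * n + nm + 1  # flux vectors, b, nadh credit

    def rsl(k: int) -> slice:
        return slice(k * n, (k + 1) * n)

    bsl = slice(nS * n, nS * n + nm)
    E_rows: list[np.ndarray] = []
    e_rhs: list[float] = []
    W_rows: list[np.ndarray] = []
    w_rhs: list[float] = []

    fixed = {fid: bounds[fid] for fid in bounds.equality_fluxes()}
    for k, sc in enumerate(printed_scenarios):
        for i in range(nm):
            row = np.zeros(nv)
            row[rsl(k)] = system.A[i]
            row[bsl][i] = -1.0
            E_rows.append(row)
            e_rhs.append(0.0)
        exact = set(sc.exact)
        for fid, (lo, hi) in fixed.items():
            row = np.zeros(nv)
            row[rsl(k)][system.flux_index(fid)] = 1.0
            E_rows.append(row)
            e_rhs.append(lo)
        if "r_ATP" in exact:
            row = np.zeros(nv)
            row[rsl(k)] = atp_row
            row[-1] = po_nadh
            E_rows.append(row)
            e_rhs.append(sc.fluxes["r_ATP"])
        for fid, val in sc.fluxes.items():
            if fid == "r_ATP":
                continue
            row = np.zeros(nv)
            row[rsl(k)][system.flux_index(fid)] = 1.0
            if fid in exact:
                E_rows.append(row)
                e_rhs.append(val)
            else:
                W_rows.append(row)
                w_rhs.append(val)
        if "r_ATP" not in exact:
            row = np.zeros(nv)
            row[rsl(k)] = atp_row
            row[-1] = po_nadh
            W_rows.append(row)
            w_rhs.append(sc.fluxes["r_ATP"])

    prior_b = prior.as_array(mets)
    for i in range(nm):
        row = np.zeros(nv)
        row[bsl][i] = ridge
        W_rows.append(row)
        w_rhs.append(ridge * prior_b[i])
    row = np.zeros(nv)
    row[-1] = ridge
    W_rows.append(row)
    w_rhs.append(ridge * prior.nadh_production)

    E = np.array(E_rows)
    e = np.array(e_rhs)
    W = np.array(W_rows)
    w = np.array(w_rhs)
    n_soft = len(w_rhs) - nm - 1

    # KKT system solved by least squares so dependent hard rows are tolerated
    H = 2.0 * W.T @ W
    K = np.block([[H, E.T], [E, np.zeros((len(E), len(E)))]])
    rhs = np.concatenate([2.0 * W.T @ w, e])
    sol, *_ = np.linalg.lstsq(K, rhs, rcond=None)
    z = sol[:nv]
    b_fit = z[bsl]
    credit = float(z[-1])

    # free directions: nullspace of the data equations (hard + soft, ridge
    # excluded); b components present there are pinned by the prior alone
    from scipy.linalg import null_space

    data_rows = np.vstack([E, W[:n_soft]]) if n_soft else E
    ns = null_space(data_rows)
    free: list[str] = []
    if ns.size:
        for i, m in enumerate(mets):
            if np.max(np.abs(ns[nS * n + i])) > 1e-8:
                free.append(m)
    if ridge == 0 and free:
        raise ScenarioError(
            "calibration underdetermined; free directions: " + ", ".join(free)
        )

    resid = W[:n_soft] @ z - w[:n_soft]
    rms = float(np.sqrt(np.mean(resid**2))) if n_soft else 0.0
    rmax = float(np.max(np.abs(resid))) if n_soft else 0.0

    used_fallback = False
    if rms > residual_threshold or np.any(b_fit < -1e-8):
        logger.warning(
            "calibration residual %.3g exceeds threshold %.3g; "
            "falling back to composition-derived loads", rms, residual_threshold
        )
        b_fit = prior_b
        credit = prior.nadh_production
        used_fallback = True
    b_fit = np.clip(b_fit, 0.0, None)

    load = LoadVector(
        mu=mu,
        b=dict(zip(mets, map(float, b_fit))),
        dna_b=dict(prior.dna_b),
        nadh_production=credit,
        atp_demand=prior.atp_demand,
        dna_atp_demand=prior.dna_atp_demand,
    )
    fitted = {
        sc.name: FluxVector(dict(zip(system.flux_order, map(float, z[rsl(k)]))))
        for k, sc in enumerate(printed_scenarios)
    }
    return CalibrationResult(
        load=load,
        residual_rms=rms,
        residual_max=rmax,
        nadh_production=credit,
        free_directions=free,
        fitted_points=fitted,
        used_fallback=used_fallback,
    )


def scenario_table_frame(table: ScenarioTable, system: StoichiometricSystem):
    """Scenario table as a tidy DataFrame (one row per LP record)."""
    import pandas as pd

    rows = []
    cluster_of = {}
    for ci, members in enumerate(table.clusters):
        for i in members:
            cluster_of[i] = ci + 1
    for i, rec in enumerate(table.records):
        row = {
            "objective": rec.objective.label,
            "cluster": cluster_of[i],
            "optimum": rec.optimum,
            "yxs": rec.yxs,
            "yxatp": rec.yxatp,
            "r_ATP": rec.r_atp,
            "r_CO2": rec.r_co2,
            "co_optimal": ";".join(o.label for o in rec.co_optimal),
            "degenerate": rec.degenerate,
        }
        for fid in system.flux_order:
            row[fid] = rec.fluxes[fid]
        rows.append(row)
    return pd.DataFrame(rows)
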
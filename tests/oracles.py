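"""Independent brute-force oracles the LP machinery is checked against.

Everything here works by exhaustive enumeration or exact arithmetic and
never calls the code under test.
"""

from __future__ import annotations

import itertools

import numpy as np
import sympy

from mipflux.network import Metabolite, Reaction, StoichiometricSystem, assemble_system
from mipflux.constraints import BoundSet
from mipflux.loads import LoadVector


def exact_rank(matrix: np.ndarray) -> int:
    """Rank by exact rational row reduction (independent of numpy)."""
    m = sympy.Matrix([[sympy.nsimplify(v, rational=True) for v in row]
                      for row in matrix])
    return m.rank()


def toy_system(
    A: np.ndarray,
    flux_ids: list[str],
    met_ids: list[str],
    reversible: tuple[str, ...] = (),
) -> StoichiometricSystem:
    """Wrap an explicit balance matrix as a stoichiometric system.

    Columns become abstract carbon-free reactions so the scenario engine can
    run on hand-built polytopes.
    """
    reactions = []
    for j, fid in enumerate(flux_ids):
        stoich = {met_ids[i]: float(A[i, j]) for i in range(len(met_ids))
                  if A[i, j] != 0}
        if not stoich:
            stoich = {met_ids[0]: 0.0}
            # a zero column would be rejected; toys always touch a balance
        reactions.append(Reaction(fid, stoich, fid in reversible))
    mets = [Metabolite(m, 0, True) for m in met_ids]
    return assemble_system(reactions, mets)


def box_cut_polytope(
    d: int, n_cuts: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Random bounded polytope: unit box plus random half-space cuts.

    Returns (A_ub, b_ub) describing {x : A_ub x <= b_ub} including the box
    faces, guaranteed non-empty (cuts keep an interior point feasible).
    """
    x0 = rng.uniform(0.3, 0.7, size=d)
    rows = []
    rhs = []
    for i in range(d):
        e = np.zeros(d)
        e[i] = 1.0
        rows += [e, -e]
        rhs += [1.0, 0.0]
    for _ in range(n_cuts):
        a = rng.standard_normal(d)
        margin = rng.uniform(0.05, 0.4)
        rows.append(a)
        rhs.append(float(a @ x0 + margin))
    return np.array(rows), np.array(rhs)


def enumerate_vertices(A_ub: np.ndarray, b_ub: np.ndarray, tol: float = 1e-9):
    """All vertices of {x : A_ub x <= b_ub} by constraint-subset intersection."""
    m, d = A_ub.shape
    verts = []
    for idx in itertools.combinations(range(m), d):
        sub = A_ub[list(idx)]
        if np.linalg.matrix_rank(sub) < d:
            continue
        x = np.linalg.solve(sub, b_ub[list(idx)])
        if np.all(A_ub @ x <= b_ub + tol):
            if not any(np.max(np.abs(x - v)) <= 1e-7 for v in verts):
                verts.append(x)
    return np.array(verts)


def polytope_as_system(
    A_ub: np.ndarray, b_ub: np.ndarray
) -> tuple[StoichiometricSystem, LoadVector, BoundSet, list[str]]:
    """Recast {A_ub x <= b_ub} in the engine's A r = b form via slacks.

    Box faces become variable bounds; every other inequality gains a slack
    flux, so vertex enumeration through the scenario engine can be compared
    with :func:`enumerate_vertices`.
    """
    m, d = A_ub.shape
    xs = [f"x{i}" for i in range(d)]
    cut_rows = []
    cut_rhs = []
    lo = np.full(d, -np.inf)
    hi = np.full(d, np.inf)
    for i in range(m):
        row = A_ub[i]
        nz = np.nonzero(row)[0]
        if len(nz) == 1:
            j = nz[0]
            if row[j] > 0:
                hi[j] = min(hi[j], b_ub[i] / row[j])
            else:
                lo[j] = max(lo[j], b_ub[i] / row[j])
        else:
            cut_rows.append(row)
            cut_rhs.append(b_ub[i])
    k = len(cut_rows)
    mets = [f"c{i}" for i in range(k)]
    A = np.zeros((k, d + k))
    for i, row in enumerate(cut_rows):
        A[i, :d] = row
        A[i, d + i] = 1.0
    fluxes = xs + [f"s{i}" for i in range(k)]
    system = toy_system(A, fluxes, mets, reversible=tuple(xs))
    load = LoadVector(mu=1.0, b={mets[i]: float(cut_rhs[i]) for i in range(k)})
    b = {xs[j]: (float(lo[j]), float(hi[j])) for j in range(d)}
    return system, load, BoundSet(b), xs
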
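"""Two-dimensional projections of the feasible flux polytope.

With two degrees of freedom left by the phenotype constraints, the feasible
set projects onto any flux pair as a convex polygon from which the two free
flux values can be chosen.  The polygon is computed by a directional LP
sweep (support function over many directions in the projection plane); for a
polytope the sweep is exact once the directions include all facet normals of
the projection, and adding directions can only grow (never shrink) the
recovered polygon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constraints import BoundSet
from .loads import LoadVector
from .network import StoichiometricSystem
from .scenarios import ScenarioTable, _LP, ScenarioError


@dataclass
class FeasibleRegion2D:
    flux_pair: tuple[str, str]
    vertices: np.ndarray  # (k, 2), counter-clockwise
    scenario_points: dict[str, tuple[float, float]] = field(default_factory=dict)
    degenerate: bool = False  # segment or point

    @property
    def area(self) -> float:
        v = self.vertices
        if len(v) < 3:
            return 0.0
        x, y = v[:, 0], v[:, 1]
        return 0.5 * float(
            np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        )


def _ccw_order(points: np.ndarray) -> np.ndarray:
    """Convex-position points ordered counter-clockwise around the centroid."""
    c = points.mean(axis=0)
    ang = np.arctan2(points[:, 1] - c[1], points[:, 0] - c[0])
    return points[np.argsort(ang)]


def _dedupe(points: np.ndarray, tol: float) -> np.ndarray:
    out: list[np.ndarray] = []
    for p in points:
        if not any(np.hypot(*(p - q)) <= tol for q in out):
            out.append(p)
    return np.array(out)


def project_pair(
    system: StoichiometricSystem,
    load: LoadVector,
    bounds: BoundSet,
    pair: tuple[str, str],
    n_directions: int = 128,
    table: ScenarioTable | None = None,
    po_nadh: float = 2.0,
    po_fadh: float = 1.0,
    tol: float = 1e-7,
) -> FeasibleRegion2D:
    """Sweep support directions to recover the projected polygon.

    Each direction solves one LP maximizing ``cos(t) x + sin(t) y``; the
    optimal vertices are deduplicated and hulled.  A projection that
    collapses to a segment or point (e.g. an equality-linked pair) is
    returned with ``degenerate=True``.
    """
    fx, fy = pair
    lp = _LP(system, load, bounds, po_nadh, po_fadh)
    jx, jy = system.flux_index(fx), system.flux_index(fy)
    pts = []
    for theta in np.linspace(0.0, 2.0 * np.pi, n_directions, endpoint=False):
        c = np.zeros(system.n_fluxes)
        c[jx] = -np.cos(theta)
        c[jy] = -np.sin(theta)
        try:
            x = lp.solve(c)
        except ScenarioError as err:
            if "unbounded" in str(err):
                raise ScenarioError(
                    f"projection of ({fx}, {fy}) unbounded along "
                    f"direction theta={theta:.3f}"
                ) from err
            raise
        pts.append((x[jx], x[jy]))
    pts = _dedupe(np.asarray(pts), tol)
    degenerate = False
    if len(pts) == 1:
        vertices = pts
        degenerate = True
    elif len(pts) == 2 or _collinear(pts, tol):
        ends = _segment_extremes(pts)
        vertices = ends
        degenerate = True
    else:
        from scipy.spatial import ConvexHull

        hull = ConvexHull(pts)
        vertices = _ccw_order(pts[hull.vertices])
    region = FeasibleRegion2D((fx, fy), np.asarray(vertices), degenerate=degenerate)
    if table is not None:
        for ci, members in enumerate(table.clusters):
            rec = table.records[members[0]]
            region.scenario_points[f"scenario {ci + 1}"] = (
                rec.fluxes[fx], rec.fluxes[fy]
            )
    return region


def _collinear(pts: np.ndarray, tol: float) -> bool:
    if len(pts) < 3:
        return True
    d = pts - pts[0]
    cross = d[1, 0] * d[2:, 1] - d[1, 1] * d[2:, 0]
    return bool(np.all(np.abs(cross) <= tol * 10))


def _segment_extremes(pts: np.ndarray) -> np.ndarray:
    d = pts - pts.mean(axis=0)
    u = d[np.argmax(np.hypot(d[:, 0], d[:, 1]))]
    u = u / (np.hypot(*u) or 1.0)
    t = d @ u
    return np.array([pts[np.argmin(t)], pts[np.argmax(t)]])


def contains_point(
    region: FeasibleRegion2D, point: tuple[float, float], tol: float = 1e-6
) -> bool:
    """True iff the point lies in the polygon inflated by ``tol``.

    Half-plane test against every counter-clockwise edge, with the slab test
    for degenerate (segment) regions.
    """
    p = np.asarray(point, dtype=float)
    v = region.vertices
    if len(v) == 1:
        return bool(np.hypot(*(p - v[0])) <= tol)
    if len(v) == 2:
        a, b = v
        ab = b - a
        L2 = float(ab @ ab)
        t = float(np.clip((p - a) @ ab / L2, 0.0, 1.0)) if L2 else 0.0
        return bool(np.hypot(*(p - (a + t * ab))) <= tol)
    for i in range(len(v)):
        a, b = v[i], v[(i + 1) % len(v)]
        edge = b - a
        d = p - a
        # z of the 2-D cross product: positive inside for CCW polygons
        if edge[0] * d[1] - edge[1] * d[0] < -tol * max(1.0, np.hypot(*edge)):
            return False
    return True


def pairwise_trend(
    points: np.ndarray | list[tuple[float, float]] | dict[str, tuple[float, float]],
) -> int:
    """Sign of the extreme-point trend for a flux pair.

    Least-squares slope through the scenario (extreme-point) coordinates:
    +1 / -1 for an increasing / decreasing relationship, 0 for flat.  Raises
    if the abscissa is degenerate (all x equal), where the trend is
    undefined.
    """
    if isinstance(points, dict):
        pts = np.array(list(points.values()), dtype=float)
    else:
        pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        raise ScenarioError("trend needs at least two points")
    x, y = pts[:, 0], pts[:, 1]
    sx = float(np.sum((x - x.mean()) ** 2))
    if sx <= 1e-12 * max(1.0, float(np.max(np.abs(x)))) ** 2:
        raise ScenarioError("trend undefined: all x values coincide")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sx)
    if abs(slope) < 1e-9:
        return 0
    return 1 if slope > 0 else -1


def region_frame(region: FeasibleRegion2D):
    """Vertices and labelled scenario points as a tidy DataFrame."""
    import pandas as pd

    fx, fy = region.flux_pair
    rows = [
        {"x": float(x), "y": float(y), "label": f"vertex {i + 1}"}
        for i, (x, y) in enumerate(region.vertices)
    ]
    rows += [
        {"x": x, "y": y, "label": label}
        for label, (x, y) in region.scenario_points.items()
    ]
    df = pd.DataFrame(rows)
    df.attrs["flux_pair"] = (fx, fy)
    return df


def plot_region(region: FeasibleRegion2D, path: str, title: str = "") -> None:
    """Optional presentation layer: shaded polygon plus labelled points."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4))
    v = region.vertices
    if len(v) >= 3:
        ax.fill(v[:, 0], v[:, 1], alpha=0.3, color="tab:gray")
    ax.plot(
        np.append(v[:, 0], v[0, 0]), np.append(v[:, 1], v[0, 1]),
        color="tab:gray",
    )
    for label, (x, y) in region.scenario_points.items():
        ax.plot(x, y, "o", color="tab:red")
        ax.annotate(label.replace("scenario ", "S"), (x, y),
                    textcoords="offset points", xytext=(4, 4), fontsize=8)
    fx, fy = region.flux_pair
    ax.set_xlabel(f"{fx} (mmol/g h)")
    ax.set_ylabel(f"{fy} (mmol/g h)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
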
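"""Phenotype measurements -> flux bounds.

The measured phenotype (growth rate, cell yield on glucose with its
resolution window, byproduct fluxes, and the admissible ATP yield range)
fixes a box of allowed fluxes: the glucose uptake window follows from the
Y_X/S window (upper yield -> lower uptake and vice versa), the gross ATP
production window from Y_X/ATP, lactate is fixed at zero, and acetate is
either fixed ("tight") or windowed ("loose").  Any flux distribution inside
the resulting polytope is macroscopically indistinguishable from any other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml


class ConstraintError(ValueError):
    pass


@dataclass(frozen=True)
class PhenotypeConstraints:
    """Measured phenotype with resolution bounds."""

    mu: float = 0.2
    yxs_range: tuple[float, float] = (0.39, 0.45)      # g cell / g glucose
    yxatp_range: tuple[float, float] = (7.0, 10.0)     # g cell / mol ATP
    acetate_mode: str = "tight"
    acetate_value: float = 1.0                         # mmol/g h (tight)
    acetate_range: tuple[float, float] = (0.8, 1.2)    # mmol/g h (loose)
    lactate_flux: float = 0.0
    po_nadh: float = 2.0
    po_fadh: float = 1.0
    glucose_mw: float = 180.0                          # g/mol
    transhydrogenase_cap: float = 0.0

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ConstraintError("mu must be positive")
        if self.po_nadh <= 0 or self.po_fadh <= 0:
            raise ConstraintError("P/O ratios must be positive")
        for name, (lo, hi) in (
            ("yxs_range", self.yxs_range),
            ("yxatp_range", self.yxatp_range),
            ("acetate_range", self.acetate_range),
        ):
            if lo > hi:
                raise ConstraintError(f"{name}: lower {lo} > upper {hi}")
        if self.acetate_mode not in ("tight", "loose"):
            raise ConstraintError(f"unknown acetate mode {self.acetate_mode!r}")


@dataclass
class BoundSet:
    """Per-flux (lower, upper) bounds; equality encoded as lower == upper.

    The key ``r_ATP`` bounds the *derived* gross ATP production (a linear
    combination of fluxes), not a standalone variable.
    """

    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for fid, (lo, hi) in self.bounds.items():
            if lo > hi:
                raise ConstraintError(f"{fid}: lower {lo} > upper {hi}")

    def __getitem__(self, fid: str) -> tuple[float, float]:
        return self.bounds[fid]

    def __contains__(self, fid: str) -> bool:
        return fid in self.bounds

    def equality_fluxes(self) -> list[str]:
        return [f for f, (lo, hi) in self.bounds.items()
                if f != "r_ATP" and lo == hi]


def glucose_bounds(
    yxs_range: tuple[float, float], mu: float, glucose_mw: float = 180.0
) -> tuple[float, float]:
    """Glucose uptake window (mmol/g h) from the yield window.

    r_glu = mu / (Y_X/S * MW) with MW in g/mmol; the upper yield maps to the
    lower flux bound.  The default window (0.39, 0.45) at mu = 0.2 gives
    (2.469, 2.849).
    """
    y_lo, y_hi = yxs_range
    if y_lo <= 0:
        raise ConstraintError("yields must be positive")
    mw = glucose_mw / 1000.0  # g/mmol
    return (mu / (y_hi * mw), mu / (y_lo * mw))


def atp_bounds(yxatp_range: tuple[float, float], mu: float) -> tuple[float, float]:
    """Gross ATP production window (mmol/g h) from the Y_X/ATP window.

    r_ATP = 1000 mu / Y_X/ATP; (7, 10) g/mol at mu = 0.2 gives (20, 28.571);
    the upper bound is carried at full precision (200/7), displayed as 28.6.
    """
    y_lo, y_hi = yxatp_range
    if y_lo <= 0:
        raise ConstraintError("yields must be positive")
    return (1000.0 * mu / y_hi, 1000.0 * mu / y_lo)


def build_bounds(constraints: PhenotypeConstraints) -> BoundSet:
    """Assemble the full measurement-derived bound set.

    Lactate fixed; acetate fixed (tight) or windowed (loose); glucose and
    ATP windows from the yields; transhydrogenase capped.  All remaining
    irreversible fluxes are bounded below by zero when the LP is built.
    """
    b: dict[str, tuple[float, float]] = {}
    b["r_LAC"] = (constraints.lactate_flux, constraints.lactate_flux)
    if constraints.acetate_mode == "tight":
        b["r_ACE"] = (constraints.acetate_value, constraints.acetate_value)
    else:
        b["r_ACE"] = constraints.acetate_range
    b["r_GLU"] = glucose_bounds(
        constraints.yxs_range, constraints.mu, constraints.glucose_mw
    )
    b["r_ATP"] = atp_bounds(constraints.yxatp_range, constraints.mu)
    b["r_TH"] = (0.0, constraints.transhydrogenase_cap)
    return BoundSet(b)


def yxs_of_glucose_flux(r_glu: float, mu: float, glucose_mw: float = 180.0) -> float:
    return mu / (r_glu * glucose_mw / 1000.0)


def yxatp_of_atp_flux(r_atp: float, mu: float) -> float:
    return 1000.0 * mu / r_atp


def load_config(path: str | Path | None = None) -> PhenotypeConstraints:
    """Read a phenotype config file (defaults bundled as paper_config.yaml)."""
    if path is None:
        path = Path(resources.files("mipflux.data") / "paper_config.yaml")
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return PhenotypeConstraints(
        mu=cfg.get("mu", 0.2),
        yxs_range=(cfg.get("yxs_low", 0.39), cfg.get("yxs_high", 0.45)),
        yxatp_range=(cfg.get("yxatp_low", 7.0), cfg.get("yxatp_high", 10.0)),
        acetate_mode=cfg.get("acetate_mode", "tight"),
        acetate_value=cfg.get("acetate_value", 1.0),
        acetate_range=tuple(cfg.get("acetate_range", (0.8, 1.2))),
        lactate_flux=cfg.get("lactate_flux", 0.0),
        po_nadh=cfg.get("po_nadh", 2.0),
        po_fadh=cfg.get("po_fadh", 1.0),
        glucose_mw=cfg.get("glucose_mw", 180.0),
        transhydrogenase_cap=cfg.get("transhydrogenase_cap", 0.0),
    )
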
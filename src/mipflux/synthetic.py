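"""Synthetic data with the statistical structure the analysis assumes.

Two generators: (i) replicated phenotype measurements (growth rate, yield,
byproduct fluxes) with Gaussian noise at stated coefficients of variation,
summarized back into resolution-bounded constraints; (ii) a protein-by-sample
abundance table emulating duplicate relative-quantitation measurements of
host versus plasmid-transformed cultures, with multiplicative (log-normal)
noise and a planted set of at-least-two-fold changes.  All draws are
reproducible bit-for-bit under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constraints import PhenotypeConstraints


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticPhenotype:
    """True phenotype plus per-measurement noise (CVs) and replication."""

    mu: float = 0.2
    yxs: float = 0.42
    acetate: float = 1.0
    lactate: float = 0.0
    cv_mu: float = 0.05
    cv_yxs: float = 0.07
    cv_acetate: float = 0.2
    cv_lactate: float = 0.0
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cv_mu", "cv_yxs", "cv_acetate", "cv_lactate"):
            if getattr(self, name) < 0:
                raise SyntheticError(f"{name} must be non-negative")
        if self.n_replicates < 1:
            raise SyntheticError("need at least one replicate")


@dataclass(frozen=True)
class SyntheticProteome:
    """Design of a synthetic differential-abundance experiment.

    ``n_down`` / ``n_up`` proteins are planted with fold changes <= 0.5 /
    >= 2.0 (the screen's own thresholds); the remainder are unchanged.  The
    40/29 default split mirrors a typical observed outcome and gives the
    fixtures a realistic imbalance.  ``noise_sd`` is the standard deviation
    of the replicate noise on the natural-log scale; ``baseline_sd`` spreads
    the per-protein baselines.
    """

    n_proteins: int = 1000
    n_down: int = 40
    n_up: int = 29
    down_range: tuple[float, float] = (0.2, 0.5)
    up_range: tuple[float, float] = (2.0, 5.0)
    noise_sd: float = 0.1
    baseline_log_mean: float = 7.0
    baseline_sd: float = 1.0
    replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_down + self.n_up > self.n_proteins:
            raise SyntheticError("more planted changes than proteins")
        if self.noise_sd < 0 or self.baseline_sd < 0:
            raise SyntheticError("noise must be non-negative")
        if not (0 < self.down_range[0] <= self.down_range[1] <= 0.5):
            raise SyntheticError(
                "down-regulated fold changes must lie in (0, 0.5]"
            )
        if not (2.0 <= self.up_range[0] <= self.up_range[1]):
            raise SyntheticError("up-regulated fold changes must be >= 2.0")
        if self.replicates < 2:
            raise SyntheticError("need at least two replicates per condition")


def generate_phenotype(spec: SyntheticPhenotype) -> pd.DataFrame:
    """Replicate measurement table: one row per (measurement, replicate)."""
    rng = np.random.default_rng(spec.seed)
    truth = {
        "mu": (spec.mu, spec.cv_mu),
        "yxs": (spec.yxs, spec.cv_yxs),
        "acetate": (spec.acetate, spec.cv_acetate),
        "lactate": (spec.lactate, spec.cv_lactate),
    }
    rows = []
    for name, (value, cv) in truth.items():
        draws = value * (1.0 + cv * rng.standard_normal(spec.n_replicates))
        for rep, v in enumerate(draws, start=1):
            rows.append({"measurement": name, "replicate": rep, "value": float(v)})
    return pd.DataFrame(rows)


def summarize_phenotype(
    table: pd.DataFrame, base: PhenotypeConstraints | None = None
) -> PhenotypeConstraints:
    """Mean +/- half-range summaries -> a resolution-bounded constraint set.

    The growth rate uses the replicate mean; yield and acetate windows span
    the replicate range (degenerate windows from noiseless replicates are
    widened to the base constraint's relative half-width).
    """
    base = base or PhenotypeConstraints()
    stats = table.groupby("measurement")["value"].agg(["mean", "min", "max"])

    def window(name: str, fallback_rel: float) -> tuple[float, float]:
        m, lo, hi = stats.loc[name]
        if hi - lo <= 1e-12 * max(1.0, abs(m)):
            half = fallback_rel * abs(m)
            return (m - half, m + half)
        return (float(lo), float(hi))

    yxs_base_rel = (base.yxs_range[1] - base.yxs_range[0]) / (
        base.yxs_range[1] + base.yxs_range[0]
    )
    mode = "tight"
    ace_lo, ace_hi = window("acetate", 0.2)
    if ace_hi - ace_lo > 1e-9:
        mode = "loose"
    return PhenotypeConstraints(
        mu=float(stats.loc["mu", "mean"]),
        yxs_range=window("yxs", yxs_base_rel),
        yxatp_range=base.yxatp_range,
        acetate_mode=mode,
        acetate_value=float(stats.loc["acetate", "mean"]),
        acetate_range=(ace_lo, ace_hi),
        lactate_flux=float(stats.loc["lactate", "mean"]),
        po_nadh=base.po_nadh,
        po_fadh=base.po_fadh,
        glucose_mw=base.glucose_mw,
        transhydrogenase_cap=base.transhydrogenase_cap,
    )


@dataclass
class ProteomeData:
    abundances: pd.DataFrame  # proteins x samples, positive
    truth: pd.DataFrame       # protein, fold_change, label

    @property
    def planted(self) -> pd.DataFrame:
        return self.truth[self.truth["label"] != "unchanged"]


def generate_proteome(spec: SyntheticProteome) -> ProteomeData:
    """Host/transformant abundance matrix with planted fold changes.

    Host replicates are log-normal around per-protein baselines; the
    transformant multiplies each baseline by its (possibly unit) fold
    change before noise.  Column names encode condition and replicate
    (``host_1``, ``transformant_2``, ...); truth labels ship alongside.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_proteins
    proteins = [f"P{i:04d}" for i in range(n)]
    baselines = np.exp(
        spec.baseline_log_mean + spec.baseline_sd * rng.standard_normal(n)
    )
    fold = np.ones(n)
    idx = rng.permutation(n)
    down = idx[: spec.n_down]
    up = idx[spec.n_down : spec.n_down + spec.n_up]
    fold[down] = rng.uniform(*spec.down_range, size=spec.n_down)
    fold[up] = rng.uniform(*spec.up_range, size=spec.n_up)
    changed = (fold <= 0.5) | (fold >= 2.0)
    if np.any(~changed & (fold != 1.0)):
        raise SyntheticError("planted fold change inside (0.5, 2.0)")

    cols = {}
    for rep in range(1, spec.replicates + 1):
        cols[f"host_{rep}"] = baselines * np.exp(
            spec.noise_sd * rng.standard_normal(n)
        )
    for rep in range(1, spec.replicates + 1):
        cols[f"transformant_{rep}"] = baselines * fold * np.exp(
            spec.noise_sd * rng.standard_normal(n)
        )
    abund = pd.DataFrame(cols, index=pd.Index(proteins, name="protein"))
    label = np.where(fold <= 0.5, "down", np.where(fold >= 2.0, "up", "unchanged"))
    truth = pd.DataFrame(
        {"fold_change": fold, "label": label},
        index=pd.Index(proteins, name="protein"),
    )
    return ProteomeData(abund, truth)
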
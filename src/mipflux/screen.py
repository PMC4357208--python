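"""Differential-abundance screen and replicate quality checks.

The screen follows the simple rule used with duplicate relative-quantitation
proteomics: a protein counts as changed when its transformant/host abundance
ratio is below 0.5 or above 2.0 *and* a two-sample t-test on log abundances
gives p < 0.05.  With two replicates per condition this is a screening
heuristic, not a calibrated test; an optional Benjamini-Hochberg correction
is available but off by default to mirror the published criterion.

The default test pools variances (the classical two-sample t).  With
duplicate samples Welch's unequal-variance correction leaves roughly one
effective degree of freedom and little power against genuine two-fold
changes; for balanced duplicate designs the pooled test is standard.
Welch's variant is available via ``welch=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class ScreenError(ValueError):
    pass


@dataclass(frozen=True)
class DifferentialResult:
    protein: str
    ratio: float
    p_value: float
    flag: str  # up | down | unchanged


def _split_columns(table: pd.DataFrame, condition: str) -> pd.DataFrame:
    cols = [c for c in table.columns if c.startswith(condition)]
    if not cols:
        raise ScreenError(f"no columns for condition {condition!r}")
    return table[cols]


def _validate(table: pd.DataFrame) -> None:
    if (table.values <= 0).any():
        raise ScreenError("abundances must be positive")


def screen(
    table: pd.DataFrame,
    ratio_low: float = 0.5,
    ratio_high: float = 2.0,
    alpha: float = 0.05,
    host: str = "host",
    transformant: str = "transformant",
    bh_fdr: bool = False,
    welch: bool = False,
) -> pd.DataFrame:
    """Apply the fold-change + t-test rule to a protein x sample table.

    Ratios are means of raw abundances (transformant over host); p-values
    come from a two-sample t-test on natural-log abundances.  Thresholds are
    strict inequalities: a ratio of exactly 1.9 is unchanged whatever its p.
    The result is invariant to rescaling all abundances by one positive
    constant.
    """
    _validate(table)
    h = _split_columns(table, host)
    t = _split_columns(table, transformant)
    if h.shape[1] < 2 or t.shape[1] < 2:
        raise ScreenError("need at least two replicates per condition")
    h_mean = h.mean(axis=1)
    if (h_mean <= 0).any():
        bad = h_mean.index[h_mean <= 0][0]
        raise ScreenError(f"zero host mean for protein {bad!r}")
    ratio = t.mean(axis=1) / h_mean
    res = stats.ttest_ind(
        np.log(t.values), np.log(h.values), axis=1, equal_var=not welch
    )
    p = pd.Series(res.pvalue, index=table.index)
    # identical replicate sets yield 0/0 t statistics; no evidence of change
    p = p.fillna(1.0)
    if bh_fdr:
        p = pd.Series(
            _benjamini_hochberg(p.values), index=p.index
        )
    flag = np.where(
        (ratio < ratio_low) & (p < alpha), "down",
        np.where((ratio > ratio_high) & (p < alpha), "up", "unchanged"),
    )
    return pd.DataFrame(
        {"ratio": ratio, "p_value": p, "flag": flag}, index=table.index
    )


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def replicate_correlation(
    table: pd.DataFrame, condition: str, log: bool = True
) -> float:
    """Pearson correlation of (log) abundances between two replicates."""
    sub = _split_columns(table, condition)
    if sub.shape[1] != 2:
        raise ScreenError(
            f"replicate correlation needs exactly 2 replicates, "
            f"got {sub.shape[1]} for {condition!r}"
        )
    _validate(sub)
    a, b = sub.values.T
    if log:
        a, b = np.log(a), np.log(b)
    r = np.corrcoef(a, b)[0, 1]
    return float(r)


def screen_metrics(
    results: pd.DataFrame, truth: pd.DataFrame
) -> dict[str, float]:
    """Recall/precision of the screen against planted truth labels."""
    merged = results.join(truth, how="inner")
    planted = merged["label"] != "unchanged"
    called = merged["flag"] != "unchanged"
    correct = planted & called & (merged["flag"] == merged["label"])
    recall = float(correct.sum() / planted.sum()) if planted.any() else float("nan")
    precision = float(correct.sum() / called.sum()) if called.any() else float("nan")
    return {
        "recall": recall,
        "precision": precision,
        "n_called": int(called.sum()),
        "n_planted": int(planted.sum()),
    }
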
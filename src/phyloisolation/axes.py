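"""Uniqueness-vs-originality decomposition of the isolation metrics.

Each metric is projected onto two interpretable axes: "uniqueness" — the
pendant edge length separating a species from the rest of the tree — and
"originality" — its mean patristic distance to all other species.  Per tree
we record, for the eight non-redundant metrics, the Spearman rank correlation
of tip scores with PE and with APD, and then fit a per-tree straight line
through the eight (rho_unique, rho_orig) points.  A strongly negative slope
means a metric aligned with one axis is weakly aligned with the other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NONREDUNDANT_METRICS",
    "TradeoffFit",
    "axis_correlations",
    "fit_axis_tradeoff",
    "aggregate_over_trees",
]

#: The eight metrics kept after dropping the redundant ones (FP ~ SV's twin
#: ED, VW ~ MVW, CHR ~ APD).
NONREDUNDANT_METRICS: tuple[str, ...] = ("PE", "SV", "ES", "MVW", "NWU", "NWW", "APD", "QE")


@dataclass(frozen=True)
class TradeoffFit:
    """Per-tree OLS of originality-correlations on uniqueness-correlations."""

    slope: float
    intercept: float
    r2_adj: float
    n_points: int


def axis_correlations(table: pd.DataFrame, metrics=NONREDUNDANT_METRICS) -> pd.DataFrame:
    """Spearman correlations of each metric with the two isolation axes.

    Returns a frame indexed by metric with columns ``rho_unique`` (vs the
    tree's PE scores) and ``rho_orig`` (vs its APD scores).  Ties get average
    ranks, which matters for the node-count metrics.  A constant score vector
    has no defined rank correlation: recorded as NaN with a warning.
    """
    if table.shape[0] < 3:
        raise ValueError("need at least three tips for rank correlations")
    missing = [m for m in list(metrics) + ["PE", "APD"] if m not in table.columns]
    if missing:
        raise KeyError(f"score table lacks metrics: {missing}")
    pe = table["PE"].to_numpy(dtype=float)
    apd = table["APD"].to_numpy(dtype=float)
    out = {}
    for m in metrics:
        v = table[m].to_numpy(dtype=float)
        if np.ptp(v) == 0 or np.ptp(pe) == 0 or np.ptp(apd) == 0:
            warnings.warn(f"constant scores make the rank correlation for {m} undefined")
            out[m] = (np.nan, np.nan)
            continue
        out[m] = (
            float(stats.spearmanr(v, pe).statistic),
            float(stats.spearmanr(v, apd).statistic),
        )
    frame = pd.DataFrame(out, index=["rho_unique", "rho_orig"]).T
    frame.index.name = "metric"
    return frame


def fit_axis_tradeoff(corrs: pd.DataFrame, response: str = "rho_unique") -> TradeoffFit:
    """Straight-line fit between the two correlation sets across metrics.

    Ordinary least squares with intercept; by default the uniqueness
    correlations are regressed on the originality correlations (the
    orientation under which the study's reported slope magnitude
    reproduces); pass ``response="rho_orig"`` for the opposite orientation.
    The adjusted R^2 (orientation-invariant) uses the simple-regression
    ``(n - 1)/(n - 2)`` correction.
    """
    if response not in ("rho_unique", "rho_orig"):
        raise ValueError("response must be 'rho_unique' or 'rho_orig'")
    clean = corrs.dropna()
    n = len(clean)
    if n < 3:
        raise ValueError("need at least three metrics with defined correlations")
    predictor = "rho_orig" if response == "rho_unique" else "rho_unique"
    x = clean[predictor].to_numpy(dtype=float)
    y = clean[response].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("predictor correlations are constant; slope undefined")
    res = stats.linregress(x, y)
    r2 = res.rvalue**2
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return TradeoffFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2_adj=float(r2_adj),
        n_points=n,
    )


def aggregate_over_trees(fits: list[TradeoffFit]) -> dict[str, float]:
    """Mean and s.d. (over trees) of the trade-off slopes and adjusted R^2."""
    if not fits:
        raise ValueError("no fits to aggregate")
    slopes = np.array([f.slope for f in fits])
    r2 = np.array([f.r2_adj for f in fits])
    sd = lambda a: float(a.std(ddof=1)) if a.size > 1 else 0.0
    return {
        "mean_slope": float(slopes.mean()),
        "sd_slope": sd(slopes),
        "mean_r2_adj": float(r2.mean()),
        "sd_r2_adj": sd(r2),
        "n_trees": len(fits),
    }
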
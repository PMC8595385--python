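"""Alpha diversity over repeated-rarefaction ensembles.

Shannon index H = -sum p_i ln p_i (natural log, so exp(H) equals the Hill
number of order 1) and Hill numbers qD = (sum p_i^q)^(1/(1-q)), with the exact
limits qD = richness at q = 0 and qD = exp(H) at q = 1. Computed per rarefied
replicate, the repetitions form an empirical distribution whose quantile band
replaces the single value a one-shot rarefaction would report.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .rarefaction import RarefiedEnsemble

__all__ = [
    "proportions",
    "shannon",
    "hill_number",
    "alpha_over_ensemble",
    "summarize_alpha",
]

ALPHA_COLUMNS = ["sample", "rep", "depth", "metric", "q", "value"]


def proportions(counts: np.ndarray) -> np.ndarray:
    """Relative abundances p_i = counts_i / library size."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("cannot form proportions of an all-zero profile")
    if counts.min() < 0:
        raise ValueError("counts must be non-negative")
    return counts / total


def shannon(counts: np.ndarray) -> float:
    """Shannon index with natural logarithm; zero counts contribute nothing."""
    p = proportions(counts)
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def hill_number(counts: np.ndarray, q: float) -> float:
    """Hill number (effective number of features) of order ``q`` >= 0.

    q = 0 is richness, q = 1 is exp(Shannon) (exact branch, not a numerical
    limit), q = 2 is the inverse Simpson concentration.
    """
    if q < 0:
        raise ValueError(f"Hill order q must be >= 0, got {q}")
    p = proportions(counts)
    p = p[p > 0]
    if q == 0:
        return float(p.size)
    if q == 1:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


def alpha_over_ensemble(
    ensemble: RarefiedEnsemble,
    metric: str = "shannon",
    q: float | list[float] | None = None,
) -> pd.DataFrame:
    """One diversity value per (rep, sample) rarefied profile.

    Returns a tidy frame with columns (sample, rep, depth, metric, q, value);
    ``q`` is NaN for the Shannon metric and may be a list for Hill numbers
    (default orders 0, 1, 2).
    """
    if metric not in ("shannon", "hill"):
        raise ValueError(f"unknown metric {metric!r}; expected 'shannon' or 'hill'")
    if metric == "shannon":
        orders: list[float | None] = [None]
    else:
        if q is None:
            orders = [0.0, 1.0, 2.0]
        else:
            orders = [float(q)] if np.isscalar(q) else [float(v) for v in q]

    stack = np.asarray(ensemble.counts)
    rows = []
    for j, s in enumerate(ensemble.sample_ids):
        for r in range(ensemble.reps):
            profile = stack[r, j]
            for order in orders:
                value = shannon(profile) if order is None else hill_number(profile, order)
                rows.append((s, r, ensemble.depth, metric, np.nan if order is None else order, value))
    return pd.DataFrame(rows, columns=ALPHA_COLUMNS)


def summarize_alpha(
    records: pd.DataFrame, lower_q: float = 0.025, upper_q: float = 0.975
) -> pd.DataFrame:
    """Collapse per-repetition records into per-(sample, depth, metric, q) bands.

    ``lower`` / ``upper`` are empirical quantiles with linear interpolation;
    the defaults give the central 95% band drawn in the diversity plots.
    """
    if records.empty:
        raise ValueError("no alpha records to summarize")
    if not 0 <= lower_q <= upper_q <= 1:
        raise ValueError("quantile bounds must satisfy 0 <= lower <= upper <= 1")
    frame = records.copy()
    frame["q"] = frame["q"].fillna(-1.0)  # groupby drops NaN keys
    grouped = frame.groupby(["sample", "depth", "metric", "q"], sort=True)["value"]
    summary = grouped.agg(
        mean="mean",
        median="median",
        lower=lambda v: float(np.quantile(v, lower_q)),
        upper=lambda v: float(np.quantile(v, upper_q)),
        n_reps="size",
    ).reset_index()
    summary["q"] = summary["q"].replace(-1.0, np.nan)
    return summary
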
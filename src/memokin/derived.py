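"""Closed-form summaries of memory T cell kinetics.

The net loss rate lambda = delta - alpha describes the decay of a
cohort of cells (and of the TCR clones it carries) in bulk: loss at
rate delta is partly offset by self-renewal at rate alpha, so the
cohort — though not its constituent cells — halves every ln2/lambda
days (the clonal half-life).  At steady state the mean cell lifespan
1/delta can also be estimated from the total production rate, either
via the early BrdU upslope (lifespan ~= 2*epsilon/p) or via Ki67
prevalence (lifespan ~= -T/ln(1 - k/2)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LifespanSummary",
    "clonal_half_life",
    "weighted_mean_lifespan",
    "lifespan_from_upslope",
    "lifespan_from_ki67",
    "weighted_subset_average",
    "estimate_upslope",
    "summarize_draws",
]


@dataclass(frozen=True)
class LifespanSummary:
    """Point summaries of one population's turnover."""

    lambda_net: float  # /day, delta - alpha
    clonal_half_life: float  # days; inf when lambda_net <= 0
    mean_lifespan: float  # days
    k: Optional[float] = None  # Ki67-high fraction
    p: Optional[float] = None  # early BrdU+ upslope, /day
    T: Optional[float] = None  # Ki67 lifetime, days
    em_cm_ratio: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mean_lifespan <= 0:
            raise ValueError("mean_lifespan must be positive")
        expected = np.inf if self.lambda_net <= 0 else np.log(2) / self.lambda_net
        if not np.isclose(self.clonal_half_life, expected, rtol=1e-9):
            raise ValueError("clonal_half_life inconsistent with lambda_net")


def clonal_half_life(delta: float, alpha: float) -> float:
    """Time for a cohort entering the population to halve, ln2/(delta-alpha).

    Returns ``inf`` when delta <= alpha: self-renewal balances or
    exceeds loss and the cohort is sustained indefinitely.
    """
    lam = delta - alpha
    if lam <= 0:
        return np.inf
    return float(np.log(2.0) / lam)


def weighted_mean_lifespan(
    loss_rates: Sequence[float], sizes: Sequence[float]
) -> float:
    """Inverse of the size-weighted mean loss rate, 1 / (sum N_i d_i / sum N_i)."""
    rates = np.asarray(loss_rates, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    if np.any(sizes < 0) or not np.any(sizes > 0):
        raise ValueError("sizes must be >= 0 with at least one positive")
    if np.any(rates[sizes > 0] <= 0):
        raise ValueError("loss rates must be positive where sizes are")
    return float(np.sum(sizes) / np.sum(sizes * rates))


def lifespan_from_upslope(p: float, epsilon: float) -> float:
    """Mean lifespan from the early BrdU labelling rate, 2*epsilon/p.

    ``p`` is the initial rate of increase of the BrdU+ fraction (/day)
    and ``epsilon`` the per-division uptake efficiency.
    """
    if p <= 0:
        raise ValueError("upslope p must be positive")
    if not (0.0 < epsilon <= 1.0):
        raise ValueError("epsilon must be in (0, 1]")
    return 2.0 * epsilon / p


def lifespan_from_ki67(k: float, T: float) -> float:
    """Mean lifespan from Ki67 prevalence, -T/ln(1 - k/2).

    ``k`` is the Ki67-high fraction and ``T`` the Ki67 lifetime in
    days.  For small k this approaches 2T/k.
    """
    if not (0.0 < k <= 1.0):
        raise ValueError("k must be in (0, 1]")
    if T <= 0:
        raise ValueError("T must be positive")
    return float(-T / np.log1p(-k / 2.0))


def weighted_subset_average(
    value_cm: float, value_em: float, em_cm_ratio: float
) -> float:
    """Abundance-weighted average over central and effector memory,
    (value_cm + ratio * value_em) / (1 + ratio)."""
    if em_cm_ratio <= 0:
        raise ValueError("em_cm_ratio must be positive")
    return (value_cm + em_cm_ratio * value_em) / (1.0 + em_cm_ratio)


def estimate_upslope(
    times: Sequence[float],
    frac_brdu: Sequence[float],
    t_max: float = 4.0,
    weights: Optional[Sequence[float]] = None,
) -> float:
    """Early BrdU+ upslope p by (weighted) least squares through the origin.

    Uses observations with t <= ``t_max`` days; the regression is
    constrained through (0, 0) since no label is present at t = 0.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(frac_brdu, dtype=float)
    w = np.ones_like(t) if weights is None else np.asarray(weights, dtype=float)
    m = (t > 0) & (t <= t_max)
    if m.sum() < 1:
        raise ValueError(f"no observations in (0, {t_max}] days")
    t, y, w = t[m], y[m], w[m]
    return float(np.sum(w * t * y) / np.sum(w * t * t))


def summarize_draws(
    draws: pd.DataFrame, quantities: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Median and 2.5/97.5 percentiles per column of a posterior draw table.

    Infinite values (e.g. clonal half-lives of draws with lambda <= 0)
    are retained; the share of such draws is reported as
    ``frac_infinite`` so that mass-at-infinity is visible next to the
    finite summaries.
    """
    cols = list(quantities) if quantities is not None else list(draws.columns)
    rows = []
    for c in cols:
        v = np.asarray(draws[c], dtype=float)
        rows.append(
            {
                "quantity": c,
                "median": float(np.median(v)),
                "q2.5": float(np.percentile(v, 2.5)),
                "q97.5": float(np.percentile(v, 97.5)),
                "frac_infinite": float(np.mean(~np.isfinite(v))),
            }
        )
    return pd.DataFrame(rows)
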
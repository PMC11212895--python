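"""Forward predictions for the two fate-mapping validation systems.

1. Reporter dilution: after tamoxifen, CD4-lineage cells heritably
   express mTom.  In a closed, self-renewing population the mTom+
   fraction stays constant; any decline reflects influx of unlabelled
   precursors.  Given fitted kinetics and an empirical description of
   the source's labelled fraction, the mTom+ timecourses of central and
   effector memory are predicted with no further free parameters.

2. Ki67 reporter transfer: cells expressing Ki67 at tamoxifen time are
   YFP-marked; three days later marked and unmarked cohorts are
   transferred, either as purified effector memory alone (no precursor
   influx) or within bulk CD4 T cells (influx preserved).  The models
   predict the decline and convergence of Ki67 within the YFP+ and
   YFP- cohorts.

Label creation by division is disabled throughout: these reporters are
heritable, so division leaves labelled fractions unchanged and only
influx moves them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit

from .datamodel import DilutionObservation
from .models import (
    KineticParameters,
    ModelTopology,
    _AffinePropagator,
    _build_system,
    _influx_split,
    stationarity_residual,
    steady_state,
    STATIONARITY_TOL,
)

__all__ = [
    "SourceCurve",
    "fit_source_dilution_curve",
    "DilutionPrediction",
    "predict_label_dilution",
    "predict_transfer_ki67",
    "TransferPrediction",
]


@dataclass(frozen=True)
class SourceCurve:
    """Smooth, monotone non-increasing labelled-fraction curve m(t).

    Forms: ``exp_plateau`` m(t) = m_inf + (m0 - m_inf) e^{-rt} with
    params (m0, m_inf, r); ``logistic`` m(t) = m_inf + (m0 - m_inf) /
    (1 + (t/t50)^h) with params (m0, m_inf, t50, h); ``constant`` with
    params (m0,).
    """

    form: str
    params: tuple
    rss: float = 0.0
    n_obs: int = 0

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if self.form == "constant":
            return np.full_like(t, self.params[0])
        if self.form == "exp_plateau":
            m0, minf, r = self.params
            return minf + (m0 - minf) * np.exp(-r * t)
        if self.form == "logistic":
            m0, minf, t50, h = self.params
            return minf + (m0 - minf) / (1.0 + (np.clip(t, 0, None) / t50) ** h)
        raise ValueError(f"unknown source curve form {self.form!r}")


def fit_source_dilution_curve(
    obs: Sequence[DilutionObservation], form: str = "exp_plateau"
) -> SourceCurve:
    """Least-squares fit of an empirical dilution curve to one subset.

    The parameterisations are constrained (m0 >= m_inf >= 0, rate >= 0)
    so the fitted curve is monotone non-increasing; on constant data
    the decay rate collapses to ~0.
    """
    t = np.array([o.t_tam for o in obs], dtype=float)
    y = np.array([o.labelled_fraction for o in obs], dtype=float)
    if form == "exp_plateau":
        n_par = 3

        def model(t, m0, dm, r):
            return (m0 - dm) + dm * np.exp(-r * t)

        if len(t) < n_par:
            raise ValueError("fewer points than parameters")
        p0 = (max(y.max(), 1e-3), max(y.max() - y.min(), 1e-4), 0.01)
        popt, _ = curve_fit(
            model, t, y, p0=p0,
            bounds=([0.0, 0.0, 0.0], [1.0, 1.0, 1.0]), maxfev=20000,
        )
        m0, dm, r = popt
        params = (float(m0), float(m0 - dm), float(r))
        resid = y - model(t, *popt)
    elif form == "logistic":
        n_par = 4

        def model(t, m0, dm, t50, h):
            return (m0 - dm) + dm / (1.0 + (np.clip(t, 0, None) / t50) ** h)

        if len(t) < n_par:
            raise ValueError("fewer points than parameters")
        p0 = (max(y.max(), 1e-3), max(y.max() - y.min(), 1e-4), max(np.median(t), 1.0), 2.0)
        popt, _ = curve_fit(
            model, t, y, p0=p0,
            bounds=([0, 0, 1e-3, 0.5], [1, 1, 1e4, 10.0]), maxfev=20000,
        )
        m0, dm, t50, h = popt
        params = (float(m0), float(m0 - dm), float(t50), float(h))
        resid = y - model(t, *popt)
    elif form == "constant":
        params = (float(np.mean(y)),)
        resid = y - params[0]
    else:
        raise ValueError(f"unknown source curve form {form!r}")
    return SourceCurve(
        form=form, params=params, rss=float(np.sum(resid**2)), n_obs=len(t)
    )


def _pool_generator(p: KineticParameters, topology: ModelTopology):
    """2x2 generator of pool-level labelled-cell counts, plus influx split."""
    G = np.array(
        [
            [p.alpha_fast - p.delta_fast, 0.0],
            [0.0, p.alpha_slow - p.delta_slow],
        ]
    )
    if topology is ModelTopology.LINEAR:
        G[0, 0] -= p.gamma
        G[1, 0] += p.gamma
    elif topology is ModelTopology.BURST:
        G[0, 0] -= p.reversion
        G[1, 0] += p.reversion
        G[0, 1] += p.activation
        G[1, 1] -= p.activation
    phi = np.array(_influx_split(p, topology))
    return G, phi


@dataclass
class DilutionPrediction:
    """Pointwise posterior band of predicted labelled fractions."""

    times: np.ndarray
    median: np.ndarray
    lo: np.ndarray  # 2.5 percentile
    hi: np.ndarray  # 97.5 percentile
    draws_total: np.ndarray  # (n_draws, n_times) whole-population fraction
    draws_fast: np.ndarray  # (n_draws, n_times) fast-pool fraction
    n_rejected: int

    def source_for_chaining(self, which: str = "total") -> list:
        """Per-draw source callables for a downstream prediction."""
        arr = self.draws_total if which == "total" else self.draws_fast
        out = []
        for row in arr:
            out.append(
                lambda t, row=row: np.interp(np.asarray(t, float), self.times, row)
            )
        return out


def predict_label_dilution(
    draws: Sequence[KineticParameters],
    topology: ModelTopology,
    source: Union[SourceCurve, Callable, Sequence[Callable]],
    times: Sequence[float],
    initial_fraction: Optional[float] = None,
    n_draws: Optional[int] = None,
    seed: int = 0,
) -> DilutionPrediction:
    """Predict reporter-label dilution in a memory subset.

    ``draws`` are stationary parameter sets (posterior draws); each is
    evolved under the subset's flow structure with division-driven
    label creation disabled and influx carrying the source's labelled
    fraction at time t.  ``source`` is a single curve, a callable, or
    one callable per draw (for chaining a downstream subset on an
    upstream prediction).  The band is the pointwise 2.5/97.5
    percentile envelope over draws.  Non-stationary draws are rejected
    and counted.
    """
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    draws = list(draws)
    if n_draws is not None and n_draws < len(draws):
        idx = rng.choice(len(draws), size=n_draws, replace=False)
        draws = [draws[i] for i in idx]
    per_draw_sources = None
    if isinstance(source, (list, tuple)):
        per_draw_sources = list(source)
        if len(per_draw_sources) < len(draws):
            raise ValueError("fewer source curves than draws")

    t_end = float(times.max())
    tot = np.full((len(draws), len(times)), np.nan)
    fast = np.full((len(draws), len(times)), np.nan)
    n_rej = 0
    for i, p in enumerate(draws):
        if np.max(np.abs(stationarity_residual(p, topology))) > STATIONARITY_TOL:
            n_rej += 1
            continue
        m = per_draw_sources[i] if per_draw_sources is not None else source
        G, phi = _pool_generator(p, topology)
        mu0 = float(m(0.0)) if initial_fraction is None else initial_fraction
        l0 = mu0 * np.array([p.N_fast, p.N_slow])

        def rhs(t, l, G=G, phi=phi, m=m):
            return G @ l + phi * float(m(t))

        sol = solve_ivp(
            rhs, (0.0, t_end), l0, t_eval=times, method="LSODA",
            rtol=1e-9, atol=1e-12,
        )
        if not sol.success:
            n_rej += 1
            continue
        tot[i] = sol.y.sum(axis=0) / p.N_total
        fast[i] = sol.y[0] / p.N_fast if p.N_fast > 0 else 0.0
    if np.all(np.isnan(tot)):
        raise ValueError(f"all {len(draws)} draws rejected as non-stationary")
    return DilutionPrediction(
        times=times,
        median=np.nanmedian(tot, axis=0),
        lo=np.nanpercentile(tot, 2.5, axis=0),
        hi=np.nanpercentile(tot, 97.5, axis=0),
        draws_total=tot,
        draws_fast=fast,
        n_rejected=n_rej,
    )


@dataclass
class TransferPrediction:
    times: np.ndarray
    ki67hi_fraction: np.ndarray
    cohort_size: np.ndarray  # relative to the whole-population size at marking


def _ki67_block(p, topology, with_influx: bool):
    """Pool x Ki67 generator (BrdU-free block of the chase-phase system)."""
    A, b = _build_system(p, topology, n_stages=1, pulse=False)
    neg = np.arange(0, A.shape[0], 2)
    M = A[np.ix_(neg, neg)]
    vec = b[neg] if with_influx else np.zeros(len(neg))
    return M, vec


def predict_transfer_ki67(
    params: KineticParameters,
    topology: ModelTopology,
    cohort: str,
    influx_on: bool,
    horizon: float = 7.0,
    times: Optional[Sequence[float]] = None,
    mark_offset: float = 3.0,
) -> TransferPrediction:
    """Ki67-high fraction of a transferred cohort over ``horizon`` days.

    The YFP+ cohort is defined as every Ki67-high cell at marking time
    (``mark_offset`` days before transfer) and the YFP- cohort as its
    complement; both evolve under the fitted dynamics until transfer,
    with influx (which is unmarked and Ki67-high) entering the YFP-
    cohort.  From transfer onward influx is retained
    (``influx_on=True``, bulk transfer with precursors present) or
    removed (isolated transfer); marked cells never receive influx.
    ``cohort`` is one of ``yfp_pos``, ``yfp_neg``, ``bulk``.
    """
    if cohort not in ("yfp_pos", "yfp_neg", "bulk"):
        raise ValueError(f"unknown cohort {cohort!r}")
    if horizon > 14.0:
        raise ValueError("horizon must be <= 14 days")
    p = params.require_closed()
    times = np.asarray(
        times if times is not None else np.linspace(0.0, horizon, 15), dtype=float
    )
    if np.any(times < 0) or np.any(times > horizon + 1e-9):
        raise ValueError("times must lie in [0, horizon]")

    ss = steady_state(p, topology, n_stages=1)
    n_pools = ss.n_pools
    occ = ss.x[::2].reshape(n_pools, 2)  # (pool, ki67) occupancies
    yfp_pos0 = occ.copy()
    yfp_pos0[:, 1] = 0.0  # marked = Ki67-high cells only
    yfp_neg0 = occ - yfp_pos0

    M, influx = _ki67_block(p, topology, with_influx=True)
    prop_full = _AffinePropagator(M, influx)
    prop_closed = _AffinePropagator(M, np.zeros(len(influx)))

    # marking -> transfer: marked cohort is closed, unmarked receives influx
    pos_t0 = prop_closed.propagate(yfp_pos0.ravel(), np.array([mark_offset]))[0]
    neg_t0 = prop_full.propagate(yfp_neg0.ravel(), np.array([mark_offset]))[0]

    post_pos = prop_closed
    post_neg = prop_full if influx_on else prop_closed
    pos_t = post_pos.propagate(pos_t0, times)
    neg_t = post_neg.propagate(neg_t0, times)

    def summarize(traj):
        v = traj.reshape(len(times), n_pools, 2)
        total = v.sum(axis=(1, 2))
        hi = v[:, :, 0].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(total > 0, hi / np.maximum(total, 1e-300), 0.0)
        return frac, total

    if cohort == "yfp_pos":
        frac, total = summarize(pos_t)
    elif cohort == "yfp_neg":
        frac, total = summarize(neg_t)
    else:
        frac, total = summarize(pos_t + neg_t)
    return TransferPrediction(
        times=times, ki67hi_fraction=frac, cohort_size=total / max(ss.total, 1e-300)
    )
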
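"""Synthetic data generation for all three experimental modalities.

Every pipeline stage is testable without external data: labelling
timecourses come from the forward ODE model with binomial counting
noise at the flow-cytometry event depth; chimerism timecourses from the
replacement model with beta noise; reporter-dilution timecourses from
the label-dilution equations.  The module also hosts an exact
event-driven stochastic (agent-based) simulation of the labelling
process, used as an independent oracle for the deterministic solver.

All generators are pure functions of (ground truth, design, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .chimerism import ReplacementParameters, replacement_curve
from .datamodel import (
    ChimerismObservation,
    Cohort,
    DilutionObservation,
    ExperimentDesign,
    LabellingObservation,
    Lineage,
    Subset,
)
from .models import (
    KineticParameters,
    ModelTopology,
    LabellingSolver,
    close_parameters,
    steady_state,
)

__all__ = [
    "GroundTruth",
    "StratumKey",
    "default_ground_truth",
    "generate_labelling_dataset",
    "generate_chimerism_dataset",
    "generate_dilution_dataset",
    "simulate_agentbased",
    "AgentBasedResult",
]

StratumKey = tuple  # (Cohort, Subset, Lineage)


@dataclass
class GroundTruth:
    """Known parameters from which synthetic datasets are generated."""

    topology: ModelTopology
    params: dict  # StratumKey -> closed KineticParameters
    replacement: dict = field(default_factory=dict)  # Subset -> ReplacementParameters
    reference_chimerism: dict = field(default_factory=dict)  # Subset -> constant
    chimerism_kappa: float = 200.0  # beta noise precision for donor fractions
    labelling_kappa: Optional[float] = None  # beta-binomial overdispersion; None = binomial
    seed: int = 0


def default_ground_truth(
    topology: ModelTopology = ModelTopology.BRANCHED,
    seed: int = 0,
) -> GroundTruth:
    """Default ground truth with realistic parameter magnitudes.

    Rates are placed inside the ranges reported for memory CD4 T cells
    in mice: fast cells turning over on timescales of days, slow cells
    with interdivision times of 100-200 d and lifespans of 60-100 d,
    Ki67 lifetime ~3.1 d, BrdU uptake efficiency ~0.6, and constitutive
    replacement of order 1-3% of the pool per day.  Central memory is
    more proliferative (higher Ki67) than effector memory; donor cells
    in young chimeras carry a larger fast-cell fraction than host
    cells, and the difference shrinks in the old cohort.
    """
    beta = 1.0 / 3.1
    eps = 0.6
    base = {
        Subset.TCM: dict(alpha_fast=0.25, alpha_slow=0.007, f=0.02,
                         pff=0.7, n_fast_frac=0.45),
        Subset.TEM: dict(alpha_fast=0.20, alpha_slow=0.005, f=0.008,
                         pff=0.4, n_fast_frac=0.20),
    }
    # fast-cell prevalence shifts: donor > host in young mice, converging in old
    fast_shift = {
        (Cohort.YOUNG, Lineage.DONOR): 1.35,
        (Cohort.YOUNG, Lineage.HOST): 0.85,
        (Cohort.OLD, Lineage.DONOR): 1.1,
        (Cohort.OLD, Lineage.HOST): 0.9,
    }
    params = {}
    for subset, b in base.items():
        for (cohort, lineage), shift in fast_shift.items():
            nf = min(b["n_fast_frac"] * shift, 0.9)
            alpha_fast = b["alpha_fast"]
            if topology is ModelTopology.TEMPORAL:
                # pools are the Ki67-high/low fractions; a non-negative
                # Ki67-low loss rate needs alpha * N_lo <= beta * N_hi
                alpha_fast = 0.6 * beta * nf / (1.0 - nf)
            raw = KineticParameters(
                epsilon=eps,
                beta=beta,
                alpha_fast=alpha_fast,
                alpha_slow=b["alpha_slow"] if topology is not ModelTopology.TEMPORAL else 0.0,
                f=b["f"],
                N_fast=nf,
                N_slow=1.0 - nf,
                phi_fast_fraction=b["pff"],
                gamma=0.01 if topology is ModelTopology.LINEAR else 0.0,
                activation=0.01 if topology is ModelTopology.BURST else 0.0,
                reversion=0.05 if topology is ModelTopology.BURST else 0.0,
            )
            params[(cohort, subset, lineage)] = close_parameters(raw, topology)
    # the replacement rate and the labelling influx f are the same
    # per-capita quantity, so the truths must agree across modalities
    replacement = {
        Subset.TCM: ReplacementParameters(
            rate=base[Subset.TCM]["f"], source_chimerism=0.72
        ),
        Subset.TEM: ReplacementParameters(
            rate=base[Subset.TEM]["f"], source_chimerism=0.62
        ),
    }
    reference = {Subset.DP1: 0.90, Subset.NAIVE_CD4: 0.78}
    return GroundTruth(
        topology=topology,
        params=params,
        replacement=replacement,
        reference_chimerism=reference,
        # between-mouse biological variability dominates counting noise in
        # replicate mice; beta-binomial overdispersion reproduces it
        labelling_kappa=500.0,
        seed=seed,
    )


def _sample_fractions(
    rng: np.random.Generator,
    mu: np.ndarray,
    n_events: Optional[int],
    kappa: Optional[float] = None,
) -> tuple[float, float, float, float]:
    """Counting noise (plus optional overdispersion) on the four fractions.

    With ``kappa`` set, each channel's per-mouse expected fraction is
    first drawn from Beta(mu*kappa, (1-mu)*kappa) — beta-binomial
    overdispersion representing between-mouse variability.  The
    Ki67-high gate is sampled first; the conditional BrdU fractions are
    sampled at the resulting gate depths; the marginal BrdU+ fraction
    is reconstituted from the three so that the additive consistency
    invariant holds exactly.
    """
    b_hi, b_lo, k = mu[1], mu[2], mu[3]
    if kappa is not None:
        def jitter(m):
            m = float(np.clip(m, 1e-9, 1 - 1e-9))
            return float(rng.beta(m * kappa, (1 - m) * kappa))

        b_hi, b_lo, k = jitter(b_hi), jitter(b_lo), jitter(k)
    if n_events is None:
        return (
            float(k * b_hi + (1.0 - k) * b_lo) if kappa is not None else float(mu[0]),
            float(b_hi), float(b_lo), float(k),
        )
    n_hi = int(rng.binomial(n_events, k))
    n_lo = n_events - n_hi
    k_hat = n_hi / n_events
    bhi_hat = rng.binomial(n_hi, b_hi) / n_hi if n_hi > 0 else 0.0
    blo_hat = rng.binomial(n_lo, b_lo) / n_lo if n_lo > 0 else 0.0
    brdu_hat = k_hat * bhi_hat + (1.0 - k_hat) * blo_hat
    return brdu_hat, bhi_hat, blo_hat, k_hat


def generate_labelling_dataset(
    truth: GroundTruth,
    design: ExperimentDesign,
    seed: Optional[int] = None,
    noise: bool = True,
    n_stages: int = 1,
) -> list[LabellingObservation]:
    """BrdU/Ki67 labelling observations for every stratum in the truth.

    For each stratum x timepoint x mouse the four summary fractions are
    computed by the forward model and perturbed by binomial sampling at
    ``design.events_per_sample`` events.  ``noise=False`` emits the
    model fractions exactly.  Deterministic given the seed.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    times = np.asarray(design.sample_times, dtype=float)
    out = []
    for key in sorted(truth.params, key=lambda k: tuple(e.value for e in k)):
        cohort, subset, lineage = key
        solver = LabellingSolver(truth.params[key], truth.topology, design, n_stages)
        mus = np.clip(solver.summaries(times), 0.0, 1.0)
        for j, t in enumerate(times):
            for m in range(design.mice_per_timepoint):
                vals = _sample_fractions(
                    rng, mus[j],
                    design.events_per_sample if noise else None,
                    kappa=truth.labelling_kappa if noise else None,
                )
                out.append(
                    LabellingObservation(
                        mouse_id=f"{cohort.value}-{subset.value}-{lineage.value}-t{t:g}-m{m}",
                        cohort=cohort,
                        subset=subset,
                        lineage=lineage,
                        t_label=float(t),
                        frac_brdu=vals[0],
                        frac_brdu_in_ki67hi=vals[1],
                        frac_brdu_in_ki67lo=vals[2],
                        frac_ki67hi=vals[3],
                        n_events=design.events_per_sample,
                    )
                )
    return out


def generate_chimerism_dataset(
    truth: GroundTruth,
    times: Sequence[float],
    mice_per_time: int = 1,
    seed: Optional[int] = None,
    noise: bool = True,
) -> list[ChimerismObservation]:
    """Donor-fraction timecourses from the replacement model, with beta noise.

    Includes constant-chimerism reference series (DP1, naive CD4) at
    the levels in ``truth.reference_chimerism``.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    times = np.asarray(times, dtype=float)
    kappa = truth.chimerism_kappa
    out = []

    def emit(subset, mu_curve):
        for j, t in enumerate(times):
            for m in range(mice_per_time):
                mu = float(np.clip(mu_curve[j], 1e-9, 1 - 1e-9))
                if noise:
                    y = float(rng.beta(mu * kappa, (1 - mu) * kappa))
                else:
                    y = mu
                out.append(
                    ChimerismObservation(
                        mouse_id=f"{subset.value}-t{t:g}-m{m}",
                        t_bmt=float(t),
                        subset=subset,
                        donor_fraction=y,
                    )
                )

    for subset in sorted(truth.replacement, key=lambda s: s.value):
        emit(subset, replacement_curve(times, truth.replacement[subset]))
    for subset in sorted(truth.reference_chimerism, key=lambda s: s.value):
        emit(subset, np.full(len(times), truth.reference_chimerism[subset]))
    return out


def generate_dilution_dataset(
    source_params: tuple,
    times: Sequence[float],
    seed: int = 0,
    noise_sd: float = 0.02,
    subset: Subset = Subset.NAIVE_CD4,
) -> list[DilutionObservation]:
    """Reporter-dilution observations from an exponential-to-plateau curve.

    ``source_params = (m0, m_inf, r)``: labelled fraction
    m(t) = m_inf + (m0 - m_inf) exp(-r t), perturbed by truncated
    Gaussian noise.
    """
    m0, minf, r = source_params
    rng = np.random.default_rng(seed)
    times = np.asarray(times, dtype=float)
    mu = minf + (m0 - minf) * np.exp(-r * times)
    ys = np.clip(mu + noise_sd * rng.standard_normal(len(times)), 0.0, 1.0)
    return [
        DilutionObservation(
            mouse_id=f"{subset.value}-t{t:g}", t_tam=float(t),
            subset=subset, labelled_fraction=float(y),
        )
        for t, y in zip(times, ys)
    ]


# ---------------------------------------------------------------------------
# exact stochastic (agent-based) oracle
# ---------------------------------------------------------------------------

_KERNEL = None


def _get_kernel():
    """Compile the SSA kernel lazily (numba import cost only when used)."""
    global _KERNEL
    if _KERNEL is not None:
        return _KERNEL
    import numba

    @numba.njit(cache=False)
    def kernel(x, alpha, delta, beta, eps, phi, trans_rate, trans_dst,
               pulse_end, rec_times, seed):
        # x: (2 pools, 2 ki67 stages, 2 brdu) int64 counts, modified in place
        np.random.seed(seed)
        n_rec = rec_times.shape[0]
        out = np.zeros((n_rec, 2, 2, 2), dtype=np.int64)
        t = 0.0
        rec = 0
        rates = np.zeros(2 * 2 * 2 * 4 + 2)  # per-comp events + influx per pool
        while rec < n_rec:
            # channel rates: per compartment [death, divide, transit, pool-switch]
            total = 0.0
            ci = 0
            for p in range(2):
                for k in range(2):
                    for b in range(2):
                        n = x[p, k, b]
                        rates[ci] = delta[p, k] * n
                        rates[ci + 1] = alpha[p] * n
                        rates[ci + 2] = beta * n if k == 0 else 0.0
                        rates[ci + 3] = trans_rate[p] * n
                        total += rates[ci] + rates[ci + 1] + rates[ci + 2] + rates[ci + 3]
                        ci += 4
            rates[ci] = phi[0]
            rates[ci + 1] = phi[1]
            total += phi[0] + phi[1]
            if total <= 0.0:
                # frozen population: emit current state at remaining times
                while rec < n_rec:
                    out[rec] = x
                    rec += 1
                break
            dt = np.random.exponential(1.0 / total)
            while rec < n_rec and t + dt > rec_times[rec]:
                out[rec] = x
                rec += 1
            if rec >= n_rec:
                break
            t += dt
            pulse = t <= pulse_end
            u = np.random.random() * total
            acc = 0.0
            ci = 0
            done = False
            for p in range(2):
                for k in range(2):
                    for b in range(2):
                        for e in range(4):
                            acc += rates[ci + e]
                            if u < acc:
                                if e == 0:  # death
                                    x[p, k, b] -= 1
                                elif e == 1:  # division
                                    x[p, k, b] -= 1
                                    if b == 1:
                                        x[p, 0, 1] += 2
                                    elif pulse and np.random.random() < eps:
                                        x[p, 0, 1] += 2
                                    else:
                                        x[p, 0, 0] += 2
                                elif e == 2:  # Ki67 high -> low
                                    x[p, 0, b] -= 1
                                    x[p, 1, b] += 1
                                else:  # pool switch
                                    x[p, k, b] -= 1
                                    x[trans_dst[p], k, b] += 1
                                done = True
                                break
                        if done:
                            break
                        ci += 4
                    if done:
                        break
                if done:
                    break
            if not done:
                # influx event
                p = 0 if u < acc + phi[0] else 1
                if pulse and np.random.random() < eps:
                    x[p, 0, 1] += 1
                else:
                    x[p, 0, 0] += 1
        return out

    _KERNEL = kernel
    return kernel


@dataclass
class AgentBasedResult:
    """Summary fractions (mean over replicates) with Monte-Carlo SEs."""

    times: np.ndarray
    mean: np.ndarray  # (n_times, 4): brdu, brdu|hi, brdu|lo, ki67hi
    se: np.ndarray
    n_reps: int
    extinct_reps: int


def simulate_agentbased(
    params: KineticParameters,
    topology: ModelTopology,
    n_cells: int,
    design: ExperimentDesign,
    times: Sequence[float],
    n_reps: int = 30,
    seed: int = 0,
) -> AgentBasedResult:
    """Exact event-driven stochastic simulation of the labelling process.

    Per-cell division (BrdU labelling with probability epsilon during
    the pulse, Ki67 reset on division), Ki67 decay, loss, constitutive
    influx and topology transitions are simulated event by event
    (single-stage Ki67 model).  Initial states are multinomial draws of
    ``n_cells`` over the BrdU-free steady-state occupancies.  Returns
    the mean and standard error of the four summary fractions over
    replicates; replicates that go extinct are counted and contribute
    only at times before extinction.
    """
    p = params.require_closed()
    if n_cells < 100:
        raise ValueError("n_cells too small for stable summaries")
    kernel = _get_kernel()
    rng = np.random.default_rng(seed)
    times = np.asarray(sorted(times), dtype=float)

    ss = steady_state(p, topology, n_stages=1)
    probs = ss.x / max(ss.total, 1e-300)
    scale = n_cells / max(p.N_total, 1e-300)

    if topology is ModelTopology.TEMPORAL:
        alpha = np.array([p.alpha_fast, 0.0])
        delta = np.array([[p.delta_fast, p.delta_slow], [0.0, 0.0]])
        phi = np.array([p.phi * scale, 0.0])
        trans_rate = np.zeros(2)
        trans_dst = np.zeros(2, dtype=np.int64)
    else:
        alpha = np.array([p.alpha_fast, p.alpha_slow])
        delta = np.array(
            [[p.delta_fast, p.delta_fast], [p.delta_slow, p.delta_slow]]
        )
        from .models import _influx_split

        phi_f, phi_s = _influx_split(p, topology)
        phi = np.array([phi_f * scale, phi_s * scale])
        trans_rate = np.zeros(2)
        trans_dst = np.zeros(2, dtype=np.int64)
        if topology is ModelTopology.LINEAR:
            trans_rate[0] = p.gamma
            trans_dst[0] = 1
        elif topology is ModelTopology.BURST:
            trans_rate[1] = p.activation
            trans_dst[1] = 0
            trans_rate[0] = p.reversion
            trans_dst[0] = 1

    fracs = np.full((n_reps, len(times), 4), np.nan)
    extinct = 0
    for r in range(n_reps):
        counts = rng.multinomial(n_cells, probs)
        if topology is ModelTopology.TEMPORAL:
            x = np.zeros((2, 2, 2), dtype=np.int64)
            x[0] = counts.reshape(2, 2)
        else:
            x = counts.reshape(2, 2, 2).astype(np.int64)
        rep_seed = int(rng.integers(0, 2**31 - 1))
        traj = kernel(
            x.copy(), alpha, delta, p.beta, p.epsilon, phi,
            trans_rate, trans_dst, design.pulse_end, times, rep_seed,
        )
        died = False
        for j in range(len(times)):
            tot = traj[j].sum()
            if tot == 0:
                died = True
                continue
            hi = traj[j][:, 0, :].sum()
            lo = traj[j][:, 1, :].sum()
            pos = traj[j][:, :, 1].sum()
            fracs[r, j] = (
                pos / tot,
                traj[j][:, 0, 1].sum() / hi if hi > 0 else np.nan,
                traj[j][:, 1, 1].sum() / lo if lo > 0 else np.nan,
                hi / tot,
            )
        extinct += died
    mean = np.nanmean(fracs, axis=0)
    n_eff = np.sum(~np.isnan(fracs), axis=0)
    se = np.nanstd(fracs, axis=0, ddof=1) / np.sqrt(np.maximum(n_eff, 1))
    return AgentBasedResult(
        times=times, mean=mean, se=se, n_reps=n_reps, extinct_reps=extinct
    )
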
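"""Shared ensemble-MCMC machinery.

Posteriors are sampled with emcee's affine-invariant ensemble sampler
(differential-evolution moves, which mix well on the correlated
posteriors that arise here).  Walkers are initialised in a small ball
around a posterior mode found by optimisation, which keeps burn-in
short.  Pointwise log-likelihoods (needed for PSIS-LOO) are collected
during sampling via emcee blobs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import emcee
import numpy as np

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import arviz as az

__all__ = ["SamplerSettings", "PosteriorSample", "run_ensemble_mcmc"]


@dataclass
class SamplerSettings:
    """Ensemble-sampler configuration.

    ``n_steps`` are post-burn-in steps; total chain length is
    ``n_burn + n_steps``.  ``thin`` reduces autocorrelation in the
    stored draws.
    """

    n_walkers: int = 32
    n_steps: int = 500
    n_burn: int = 300
    thin: int = 4
    n_optim_starts: int = 4
    rhat_threshold: float = 1.05


@dataclass
class PosteriorSample:
    """Draws and diagnostics from one ensemble run.

    ``draws`` has shape (n_kept, ndim) on the sampling (transformed)
    scale; ``pointwise_loglik`` is (n_kept, n_obs) when the model
    reported per-observation likelihoods.
    """

    draws: np.ndarray
    log_prob: np.ndarray
    pointwise_loglik: Optional[np.ndarray]
    param_names: list
    rhat: dict
    ess: dict
    converged: bool
    seed: int
    chain: np.ndarray = field(repr=False, default=None)  # (chains, steps, ndim)

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    def to_inference_data(self) -> az.InferenceData:
        posterior = {
            name: self.chain[:, :, i] for i, name in enumerate(self.param_names)
        }
        groups = {"posterior": posterior}
        if self.pointwise_loglik is not None:
            n_chains, n_steps, _ = self.chain.shape
            ll = self.pointwise_loglik.reshape(n_chains, n_steps, -1)
            groups["log_likelihood"] = {"obs": ll}
        return az.from_dict(**groups)


def _find_mode(
    log_post: Callable,
    draw_start: Callable[[np.random.Generator], np.ndarray],
    rng: np.random.Generator,
    n_starts: int,
) -> np.ndarray:
    from scipy.optimize import minimize

    def neg(x):
        v = log_post(x)
        if isinstance(v, tuple):
            v = v[0]
        return -v if np.isfinite(v) else 1e12

    best_x, best_v = None, np.inf
    for _ in range(n_starts):
        x0 = draw_start(rng)
        if not np.isfinite(neg(x0)):
            continue
        res = minimize(neg, x0, method="Nelder-Mead",
                       options={"maxiter": 800, "xatol": 1e-4, "fatol": 1e-4})
        if res.fun < best_v:
            best_x, best_v = res.x, res.fun
    if best_x is None:
        raise RuntimeError("no finite starting point found for the sampler")
    return best_x


def _laplace_cov(log_post: Callable, mode: np.ndarray) -> Optional[np.ndarray]:
    """Inverse negative Hessian at the mode, or None if not usable.

    Used only to spread the initial walker ensemble roughly over the
    posterior bulk, which shortens burn-in considerably.
    """
    ndim = len(mode)

    def lp(x):
        v = log_post(x)
        return v[0] if isinstance(v, tuple) else v

    h = 1e-4
    H = np.empty((ndim, ndim))
    f0 = lp(mode)
    if not np.isfinite(f0):
        return None
    fp = np.empty(ndim)
    fm = np.empty(ndim)
    for i in range(ndim):
        ei = np.zeros(ndim)
        ei[i] = h
        fp[i] = lp(mode + ei)
        fm[i] = lp(mode - ei)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h**2
    for i in range(ndim):
        for j in range(i + 1, ndim):
            ei = np.zeros(ndim)
            ej = np.zeros(ndim)
            ei[i] = h
            ej[j] = h
            fpp = lp(mode + ei + ej)
            fmm = lp(mode - ei - ej)
            H[i, j] = H[j, i] = (
                fpp - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + fmm
            ) / (2 * h**2)
    if not np.all(np.isfinite(H)):
        return None
    try:
        cov = np.linalg.inv(-H)
        w, V = np.linalg.eigh(cov)
        w = np.clip(w, 1e-10, 1.0)  # guard flat/negative directions
        return (V * w) @ V.T
    except np.linalg.LinAlgError:
        return None


def run_ensemble_mcmc(
    log_post: Callable,
    param_names: Sequence[str],
    draw_start: Callable[[np.random.Generator], np.ndarray],
    seed: int,
    settings: Optional[SamplerSettings] = None,
    has_blobs: bool = False,
    n_obs: int = 0,
) -> PosteriorSample:
    """Sample ``log_post`` and return draws with convergence diagnostics.

    ``log_post(theta)`` returns either a float or, when ``has_blobs``,
    a tuple ``(logp, pointwise_loglik_vector)``.  ``draw_start`` maps an
    RNG to one overdispersed starting point (typically a prior draw).
    """
    s = settings or SamplerSettings()
    ndim = len(param_names)
    n_walkers = max(s.n_walkers, 2 * ndim + 2)
    rng = np.random.default_rng(seed)

    mode = _find_mode(log_post, draw_start, rng, s.n_optim_starts)
    cov = _laplace_cov(log_post, mode)
    if cov is not None:
        L = np.linalg.cholesky(cov + 1e-12 * np.eye(ndim))
        p0 = mode + rng.standard_normal((n_walkers, ndim)) @ L.T
    else:
        p0 = mode + 1e-3 * rng.standard_normal((n_walkers, ndim))
    # ensure all walkers start at finite posterior density
    for i in range(n_walkers):
        for _ in range(100):
            v = log_post(p0[i])
            lp = v[0] if isinstance(v, tuple) else v
            if np.isfinite(lp):
                break
            p0[i] = mode + 1e-3 * rng.standard_normal(ndim)

    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    blobs_dtype = [("loglik", float, (n_obs,))] if has_blobs else None
    sampler = emcee.EnsembleSampler(
        n_walkers, ndim, log_post, moves=moves, blobs_dtype=blobs_dtype
    )
    # the setter expects a get_state() tuple and fails silently otherwise
    sampler.random_state = np.random.RandomState(seed).get_state()
    sampler.run_mcmc(p0, s.n_burn + s.n_steps, progress=False, skip_initial_state_check=True)

    chain = sampler.get_chain(discard=s.n_burn, thin=s.thin)  # (steps, walkers, dim)
    chain = np.moveaxis(chain, 0, 1)  # (walkers, steps, dim)
    draws = chain.reshape(-1, ndim)
    logp = np.moveaxis(
        sampler.get_log_prob(discard=s.n_burn, thin=s.thin), 0, 1
    ).reshape(-1)

    pointwise = None
    if has_blobs:
        blobs = sampler.get_blobs(discard=s.n_burn, thin=s.thin)["loglik"]
        pointwise = np.moveaxis(blobs, 0, 1).reshape(-1, n_obs)

    # ensemble walkers are coupled, not independent chains: group them
    # into four pseudo-chains for a stable split-Rhat, and pool all
    # draws for the ESS estimate.
    n_groups = 4
    g = (n_walkers // n_groups) * n_groups
    kept = chain.shape[1]
    grouped = chain[:g].reshape(n_groups, -1, kept, ndim).reshape(n_groups, -1, ndim)
    post = {name: grouped[:, :, i] for i, name in enumerate(param_names)}
    post_full = {name: chain[:, :, i] for i, name in enumerate(param_names)}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat_ds = az.rhat(az.from_dict(posterior=post))
        ess_ds = az.ess(az.from_dict(posterior=post_full))
    rhat = {k: float(rhat_ds[k].values) for k in param_names}
    ess = {k: float(ess_ds[k].values) for k in param_names}
    converged = all(np.isfinite(v) and v < s.rhat_threshold for v in rhat.values())

    return PosteriorSample(
        draws=draws,
        log_prob=logp,
        pointwise_loglik=pointwise,
        param_names=list(param_names),
        rhat=rhat,
        ess=ess,
        converged=converged,
        seed=seed,
        chain=chain,
    )
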
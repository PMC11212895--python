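"""Bayesian fitting machinery: priors, likelihood, LOO and comparison."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit

from memokin._mcmc import SamplerSettings, run_ensemble_mcmc
from memokin.datamodel import ExperimentDesign
from memokin.inference import (
    ELPD_INDISTINGUISHABLE,
    PriorSpec,
    compare_models,
    compare_pointwise,
    fit_labelling_model,
)
from memokin.models import ModelTopology


class TestPriorOnly:
    def test_posterior_reproduces_prior_quantiles(self, stratum_obs, design):
        fit = fit_labelling_model(
            stratum_obs, ModelTopology.BRANCHED, prior_only=True,
            settings=SamplerSettings(n_walkers=32, n_steps=400, n_burn=300, thin=4),
            seed=3, design=design,
        )
        draws = fit.sample.draws
        names = fit.sample.param_names
        spec = PriorSpec()
        # parameters unaffected by the fast/slow ordering truncation
        for name in ("log_beta", "logit_epsilon", "log_f", "logit_nfast"):
            mu, sd = spec.mu_sd(name)
            x = draws[:, names.index(name)]
            for q, expected in zip(
                (0.25, 0.5, 0.75), stats.norm.ppf([0.25, 0.5, 0.75], mu, sd)
            ):
                assert np.quantile(x, q) == pytest.approx(
                    expected, abs=0.15 * sd + 0.05
                )


class TestLikelihoodSanity:
    def test_truth_beats_perturbed_rates(self, design, stratum_params, branched_truth):
        """On noise-free data the log-likelihood peaks at the generating
        parameters rather than at +50% single-rate perturbations."""
        import dataclasses

        from memokin.synthetic import GroundTruth, generate_labelling_dataset
        from memokin.inference import _beta_logpdf
        from memokin.models import LabellingSolver, close_parameters

        truth = GroundTruth(
            topology=ModelTopology.BRANCHED,
            params={(*branched_truth.params,)[0]: stratum_params},
        )
        key = next(iter(truth.params))
        obs = generate_labelling_dataset(truth, design, seed=0, noise=False)
        ts = np.array(sorted({o.t_label for o in obs}))
        y = np.array(
            [[o.frac_brdu_in_ki67hi, o.frac_brdu_in_ki67lo, o.frac_ki67hi]
             for o in sorted(obs, key=lambda o: o.t_label)]
        )
        t_sorted = np.array([o.t_label for o in sorted(obs, key=lambda o: o.t_label)])

        def loglik(p):
            mu = LabellingSolver(p, ModelTopology.BRANCHED, design).summaries(ts)
            mu = np.clip(mu, 1e-6, 1 - 1e-6)
            idx = np.searchsorted(ts, t_sorted)
            m = mu[idx][:, [1, 2, 3]]
            kappa = 500.0
            return float(
                _beta_logpdf(np.clip(y, 1e-6, 1 - 1e-6), m * kappa, (1 - m) * kappa).sum()
            )

        base = loglik(stratum_params)
        for field in ("alpha_fast", "alpha_slow", "f", "beta"):
            perturbed = dataclasses.replace(
                stratum_params,
                **{field: getattr(stratum_params, field) * 1.5},
                delta_fast=None, delta_slow=None,
            )
            perturbed = close_parameters(perturbed, ModelTopology.BRANCHED)
            assert loglik(perturbed) < base


class TestCompare:
    def test_self_comparison_is_indistinguishable(self, stratum_fit):
        cmp = compare_pointwise(
            ["a", "b"], [stratum_fit.loo_pointwise, stratum_fit.loo_pointwise]
        )
        row = cmp.pairwise.iloc[0]
        assert row.delta_elpd == 0.0
        assert row.indistinguishable

    def test_mismatched_data_rejected(self, stratum_fit, design, branched_truth):
        from memokin.synthetic import generate_labelling_dataset

        other_obs = generate_labelling_dataset(branched_truth, design, seed=9)
        other_obs = [
            o for o in other_obs
            if (o.cohort, o.subset, o.lineage) == stratum_fit.stratum
        ]
        import dataclasses

        other = dataclasses.replace(stratum_fit, observations=other_obs)
        with pytest.raises(ValueError, match="different observation"):
            compare_models([stratum_fit, other])

    def test_threshold_flag(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 0.1, 50)
        close = base + ELPD_INDISTINGUISHABLE / 50 * 0.5  # total delta = 2
        far = base - ELPD_INDISTINGUISHABLE / 50 * 3  # total delta = 12
        cmp = compare_pointwise(["a", "b", "c"], [base, close, far])
        assert cmp.indistinguishable("a", "b")
        assert not cmp.indistinguishable("a", "c")


class TestLooAgainstExactRefit:
    def test_psis_loo_matches_exact_loo_on_toy(self):
        """PSIS-LOO ELPD agrees with brute-force leave-one-out refitting
        within 2 SE on a 10-observation linear-Gaussian toy."""
        rng = np.random.default_rng(11)
        n = 10
        x = np.linspace(0, 1, n)
        y = 1.0 + 2.0 * x + 0.3 * rng.standard_normal(n)
        sigma = 0.3

        def make_logpost(xs, ys):
            def log_post(theta):
                a, b = theta
                mu = a + b * xs
                ll = stats.norm.logpdf(ys, mu, sigma)
                lp = stats.norm.logpdf(a, 0, 5) + stats.norm.logpdf(b, 0, 5)
                return float(lp + ll.sum()), stats.norm.logpdf(y, a + b * x, sigma)

            return log_post

        settings = SamplerSettings(n_walkers=16, n_steps=600, n_burn=400, thin=4)
        full = run_ensemble_mcmc(
            make_logpost(x, y), ["a", "b"],
            lambda r: r.standard_normal(2), seed=1, settings=settings,
            has_blobs=True, n_obs=n,
        )
        import arviz as az

        idata = full.to_inference_data()
        loo = az.loo(idata, pointwise=True)

        exact = 0.0
        for i in range(n):
            keep = np.arange(n) != i
            refit = run_ensemble_mcmc(
                make_logpost(x[keep], y[keep]), ["a", "b"],
                lambda r: r.standard_normal(2), seed=100 + i, settings=settings,
                has_blobs=True, n_obs=n,
            )
            ll_i = refit.pointwise_loglik[:, i]
            exact += float(np.log(np.mean(np.exp(ll_i))))
        assert float(loo.elpd_loo) == pytest.approx(exact, abs=2 * float(loo.se))


class TestIdentifiabilityToy:
    def test_orthogonal_design_uncorrelated(self):
        """Independent Gaussian observations of independent parameters
        leave no posterior correlation."""
        rng = np.random.default_rng(2)
        y1 = 1.0 + 0.1 * rng.standard_normal(40)
        y2 = -0.5 + 0.1 * rng.standard_normal(40)

        def log_post(theta):
            a, b = theta
            return float(
                stats.norm.logpdf(y1, a, 0.1).sum()
                + stats.norm.logpdf(y2, b, 0.1).sum()
                + stats.norm.logpdf(a, 0, 10)
                + stats.norm.logpdf(b, 0, 10)
            )

        sample = run_ensemble_mcmc(
            log_post, ["a", "b"], lambda r: r.standard_normal(2), seed=5,
            settings=SamplerSettings(n_walkers=16, n_steps=800, n_burn=400, thin=4),
        )
        corr = np.corrcoef(sample.draws[:, 0], sample.draws[:, 1])[0, 1]
        assert abs(corr) < 0.1


class TestPosteriorQuality:
    def test_epsilon_posterior_is_narrow(self, stratum_fit):
        # labelled fractions within Ki67-high cells bound the uptake
        # efficiency tightly
        nat = stratum_fit.posterior_params()
        assert nat["epsilon"].std() <= 0.1

    def test_posterior_predictive_covers_held_in_observations(self, stratum_fit):
        """95% posterior-predictive intervals cover >=90% of the fitted
        observations across the three likelihood channels."""
        from memokin.models import LabellingSolver

        obs = stratum_fit.observations
        design = ExperimentDesign()
        nat = stratum_fit.posterior_params()
        rng = np.random.default_rng(0)
        idx = rng.choice(len(nat), size=150, replace=False)
        ts = np.array(sorted({o.t_label for o in obs}))
        preds = []  # per draw: predictive samples at each time/channel
        from memokin.pipeline import _params_from_natural_row

        for i in idx:
            row = nat.iloc[i]
            p = _params_from_natural_row(row, ModelTopology.BRANCHED)
            mu = np.clip(
                LabellingSolver(p, ModelTopology.BRANCHED, design).summaries(ts),
                1e-6, 1 - 1e-6,
            )
            kap = [row["kappa_brdu_in_ki67hi"], row["kappa_brdu_in_ki67lo"], row["kappa_ki67hi"]]
            draw = np.empty((len(ts), 3))
            for c, (col, kc) in enumerate(zip((1, 2, 3), kap)):
                draw[:, c] = rng.beta(mu[:, col] * kc, (1 - mu[:, col]) * kc)
            preds.append(draw)
        preds = np.array(preds)  # (draws, times, channels)
        lo = np.percentile(preds, 2.5, axis=0)
        hi = np.percentile(preds, 97.5, axis=0)
        t_pos = {t: j for j, t in enumerate(ts)}
        covered, total = 0, 0
        for o in obs:
            j = t_pos[o.t_label]
            vals = (o.frac_brdu_in_ki67hi, o.frac_brdu_in_ki67lo, o.frac_ki67hi)
            for c, v in enumerate(vals):
                covered += int(lo[j, c] <= v <= hi[j, c])
                total += 1
        assert covered / total >= 0.90
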
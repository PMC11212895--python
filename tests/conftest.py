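"""Shared fixtures: study design, realistic ground truths, seeded data."""

import warnings

import numpy as np
import pytest

from memokin.datamodel import Cohort, ExperimentDesign, Lineage, Subset
from memokin.models import ModelTopology
from memokin.synthetic import GroundTruth, generate_labelling_dataset, default_ground_truth

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=RuntimeWarning)

#: The stratum used for single-stratum fitting experiments throughout.
STRATUM = (Cohort.YOUNG, Subset.TCM, Lineage.DONOR)


@pytest.fixture(scope="session")
def design():
    return ExperimentDesign()


@pytest.fixture(scope="session")
def branched_truth():
    return default_ground_truth(ModelTopology.BRANCHED)


@pytest.fixture(scope="session")
def stratum_params(branched_truth):
    """Closed realistic parameters of the reference stratum."""
    return branched_truth.params[STRATUM]


@pytest.fixture(scope="session")
def stratum_obs(stratum_params, design):
    """One seeded synthetic timecourse for the reference stratum."""
    truth = GroundTruth(
        topology=ModelTopology.BRANCHED,
        params={STRATUM: stratum_params},
        labelling_kappa=500.0,
    )
    return generate_labelling_dataset(truth, design, seed=42)


@pytest.fixture(scope="session")
def informative_influx_prior(stratum_params):
    """Influx prior of replacement-fit strength, centred on the truth."""
    from memokin.chimerism import InfluxPrior

    return InfluxPrior(
        family="lognormal",
        meanlog=float(np.log(stratum_params.f)),
        sdlog=0.05,
        chimerism_a=2.0,
        chimerism_b=2.0,
    )


@pytest.fixture(scope="session")
def stratum_fit(stratum_obs, design, informative_influx_prior):
    """A converged branched-model fit of the reference stratum (shared:
    MCMC is the expensive step, so several tests reuse this posterior)."""
    from memokin._mcmc import SamplerSettings
    from memokin.inference import PriorSpec, fit_labelling_model

    return fit_labelling_model(
        stratum_obs,
        ModelTopology.BRANCHED,
        priors=PriorSpec(influx_prior=informative_influx_prior),
        settings=SamplerSettings(n_walkers=32, n_steps=500, n_burn=350, thin=4),
        seed=7,
        design=design,
    )
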
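import numpy as np
import pytest
from hypothesis import settings

from asfintake.model import ModelSpec, build_design, fit, predict_strata
from asfintake.synthdata import SurveyDesign, TruthConfig, simulate_world

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def world():
    """A moderate synthetic study: 4 regions x 5 countries, 2 surveys each."""
    return simulate_world(TruthConfig(), SurveyDesign(), seed=7)


@pytest.fixture(scope="session")
def milk_fit(world):
    design = build_design(
        world.surveys, world.covariates, weights=world.weights, asf="milk"
    )
    return fit(design, ModelSpec(n_draws=1000, chains=2, warmup=400, seed=1))


@pytest.fixture(scope="session")
def milk_draws(world, milk_fit):
    targets = [(c, y) for c in world.truth.countries for y in (1990, 2018)]
    return predict_strata(milk_fit, targets)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
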
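import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from triarm import (
    BayesianOutcomeModel,
    PosteriorDraws,
    generate_trial,
    reference_config,
)
from triarm.results import OutcomeResults


@pytest.fixture(scope="session")
def ref_config():
    return reference_config()


@pytest.fixture(scope="session")
def ref_dataset(ref_config):
    return generate_trial(ref_config, seed=11)


@pytest.fixture(scope="session")
def spic_fit(ref_dataset):
    """A modest shared fit of the postSPIC model on the reference trial."""
    model = BayesianOutcomeModel.from_dataset("postSPIC", ref_dataset)
    return model.fit(chains=4, iterations=800, warmup=400, seed=21)


def degenerate_results(dataset, outcome, theta, n_draws=64, chains=2):
    """OutcomeResults whose posterior is a point mass at ``theta`` —
    useful for algebraic checks without sampling noise."""
    model = BayesianOutcomeModel.from_dataset(outcome, dataset)
    vec = model.params_to_vector(theta) if hasattr(theta, "mu") else np.asarray(theta)
    draws = np.tile(vec, (chains, n_draws, 1))
    return OutcomeResults(model, PosteriorDraws(model.param_names, draws))


@pytest.fixture
def make_degenerate_results(ref_dataset):
    def _make(outcome, params, **kw):
        return degenerate_results(ref_dataset, outcome, params, **kw)

    return _make
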
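"""Shared fixtures: small synthetic bundles reused across the suite."""

import warnings

import pytest

# statsmodels / arviz are imported lazily inside the sampler; importing them
# here keeps their one-off import cost out of individual test timings
import statsmodels.api  # noqa: F401

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import arviz  # noqa: F401

from mortgap.model import McmcConfig, ModelSpec, sample_posterior
from mortgap.synthetic import make_fixture


@pytest.fixture(scope="session")
def tiny_bundle():
    """(truth, covariates, table) on the 72-cell grid, male lung cancer."""
    return make_fixture("tiny", seed=11)


@pytest.fixture(scope="session")
def tiny_spec():
    return ModelSpec(cause="LC", sex="M")


@pytest.fixture(scope="session")
def tiny_draws(tiny_bundle, tiny_spec):
    """A converged-ish posterior on the tiny fixture, reused where the
    specific seed does not matter."""
    _, covariates, table = tiny_bundle
    mcmc = McmcConfig(chains=2, iterations=2000, burn_in=1000, thin=2,
                      seed=11)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sample_posterior(tiny_spec, table, covariates, mcmc)
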
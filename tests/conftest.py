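import warnings

import numpy as np
import pytest

import fcrank as fc

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@pytest.fixture(scope="session")
def fast_mcmc():
    """Reduced sampler settings for unit tests that only need a usable
    posterior, not publication-grade effective sample sizes."""
    return fc.McmcConfig(chains=4, draws_per_chain=500, warmup=2500, thin=10,
                         rhat_threshold=1.05)


@pytest.fixture(scope="session")
def linear_t3_fit(fast_mcmc):
    """One fitted linear-sensitive cohort (T=3, n=1500, delta*=2) shared
    across model-level tests."""
    truth = fc.GroundTruth.make("linear", 3, 2.0)
    data = fc.simulate_dataset(truth, 1500, seed=11)
    draws = fc.fit(data, fc.PriorConfig(), fast_mcmc)
    return truth, data, draws


@pytest.fixture(scope="session")
def full_study():
    """The full 108-cell operating-characteristics study at the default
    desk-scale sampler settings, shared by the acceptance tests."""
    return fc.run_study(master_seed=2026)
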
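import numpy as np
import pytest

from crbench.simulate import CensoringSpec, ScenarioSpec, simulate_dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def linear_sample():
    """One moderate linear-scenario dataset with the default ~25% censoring."""
    return simulate_dataset(ScenarioSpec(kind="linear", n=300), seed=11)


@pytest.fixture(scope="session")
def null_sample_uncensored():
    return simulate_dataset(
        ScenarioSpec(kind="null", n=400, censoring=CensoringSpec(kind="none")),
        seed=7)


def random_competing_sample(rng, n, censor_frac=0.2, p_cause1=0.5):
    """Small unstructured competing-risks sample for metric/split oracles."""
    from crbench.simulate import CompetingRisksSample, draw_covariates

    X = draw_covariates(n, rng)
    time = rng.exponential(50.0, size=n)
    event = np.where(rng.random(n) < censor_frac, 0,
                     np.where(rng.random(n) < p_cause1, 1, 2))
    if not (event == 1).any():
        event[int(rng.integers(n))] = 1
    return CompetingRisksSample(X, time, event)
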
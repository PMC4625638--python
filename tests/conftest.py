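import numpy as np
import pytest

from omicox import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def cohort():
    """One medium synthetic cohort shared by read-only tests."""
    return generate_cohort(SyntheticConfig(n_patients=150, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_survival(rng, n, censor_frac=0.3):
    """Small random survival instance with tie-free times."""
    from omicox import SurvivalData

    time = rng.exponential(100.0, size=n) + rng.uniform(0, 1e-3, size=n)
    event = (rng.random(n) > censor_frac).astype(int)
    if event.sum() == 0:
        event[int(rng.integers(n))] = 1
    return SurvivalData([f"P{i}" for i in range(n)], time, event)
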
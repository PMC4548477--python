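import numpy as np
import pytest

from normrisk.datasets import synthetic_case_study
from normrisk.model import summarize_sample


@pytest.fixture(scope="session")
def case_samples():
    """Moment-matched synthetic case-study samples (exposure, effect)."""
    return synthetic_case_study()


@pytest.fixture(scope="session")
def case_stats(case_samples):
    x, y = case_samples
    return summarize_sample(x, "exposure"), summarize_sample(y, "effect")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
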
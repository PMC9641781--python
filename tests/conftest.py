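import numpy as np
import pytest

from endomr.mr_core import MRInput


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_mrinput(rng, j=10, theta=0.1, het=0.0):
    """Random but well-behaved summary-data input for estimator tests."""
    beta_x = rng.uniform(0.03, 0.12, j)
    se_x = rng.uniform(0.003, 0.008, j)
    se_y = rng.uniform(0.005, 0.02, j)
    beta_y = theta * beta_x + rng.normal(0, se_y) + rng.normal(0, het, j)
    return MRInput(
        rsid=tuple(f"rs{i}" for i in range(j)),
        beta_x=beta_x, se_x=se_x, beta_y=beta_y, se_y=se_y,
    )


@pytest.fixture
def mrinput_factory():
    return random_mrinput
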
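import warnings

import numpy as np
import pytest

from chromaqc.pipeline import RunConfig, run_qc

# designed-linear retention times of the synthetic 29-peak profile
LINEAR_CENTERS = [
    7.28, 8.73, 9.02, 9.30, 9.80, 10.43, 11.99, 12.53, 12.76, 13.18, 14.35,
    17.18, 18.95, 19.33, 20.27, 20.87, 21.33, 21.75, 22.12, 22.70, 23.13,
    23.65, 24.20,
]


@pytest.fixture(scope="session")
def qc_run_seed1():
    """One full pipeline run (seed 1, with validation) shared across tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_qc(RunConfig(seed=1, validate=True))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
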
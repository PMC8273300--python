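import warnings

import numpy as np
import pytest

from himasurv import PipelineConfig, SimConfig, calibrate_censoring, generate_dataset, run_pipeline


@pytest.fixture(scope="session")
def c0_15():
    """Censoring bound for the 15% target under default coefficients."""
    return calibrate_censoring(SimConfig(n_subjects=100, n_mediators=10),
                               target=0.15, rng=np.random.default_rng(101))


@pytest.fixture(scope="session")
def small_dataset(c0_15):
    """One modest simulated dataset (n=300, p=120) shared across unit tests."""
    cfg = SimConfig(n_subjects=300, n_mediators=120, target_censoring=0.15,
                    c0=c0_15, seed=7)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_pipeline_result(small_dataset):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(small_dataset, PipelineConfig(mode="ps"))
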
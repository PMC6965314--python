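import numpy as np
import pytest

from gfcpipe.gfcmetric import gray_matter_mask
from gfcpipe.simdata import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact planted-effect cohort reused across read-only tests."""
    cfg = SimConfig(
        n_patients=6, n_controls=6, n_volumes=120, effect_delta=0.4, seed=123
    )
    subjects, truth = generate_cohort(cfg)
    return cfg, subjects, truth


@pytest.fixture(scope="session")
def small_gm(small_cohort):
    _, _, truth = small_cohort
    return gray_matter_mask(truth.gm_prob, 0.2)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
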
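import warnings

import pytest

import restraintopt as ro
from restraintopt.doe import campaign_design, scale_design

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings(
    "ignore", module="sklearn.gaussian_process"
)


@pytest.fixture(scope="session")
def sedan_cfg():
    return ro.sedan_config()


@pytest.fixture(scope="session")
def small_records(sedan_cfg):
    """120 noiseless campaign runs on a MaxPro design (shared across tests)."""
    dm = campaign_design(120, seed=101, iterations=4000)
    return ro.generate_dataset(scale_design(dm), sedan_cfg, seed=7, noisy=False)


@pytest.fixture(scope="session")
def small_model(small_records):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ro.fit_gp(small_records, seed=0, n_restarts=0)
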
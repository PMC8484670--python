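import numpy as np
import pytest

from tamodel.fitting import OptConfig, TimeCourse
from tamodel.model import ZParams
from tamodel.synthetic import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def example_params() -> ZParams:
    """A well-behaved parameter set with every feedback active."""
    return ZParams(
        k1=3.0, k2=1.0, d1=2.0, d2=0.3, d3=1.0,
        s1=0.1, s2=2.0, bm=1.0, bc=1.0, c0=1.0,
    )


@pytest.fixture(scope="session")
def cheap_opt() -> OptConfig:
    """A minimal optimiser budget for contract (not quality) tests."""
    return OptConfig(n_hops=1, local_maxiter=60, ls_max_nfev=40)


@pytest.fixture(scope="session")
def small_dataset():
    """Three noiseless pairs (2 central + 1 outlier) on the default grid."""
    cfg = GeneratorConfig(n_central=2, n_outliers=1, master_seed=42)
    timecourses, truth = generate_dataset(cfg)
    return cfg, timecourses, truth


@pytest.fixture()
def toy_timecourse() -> TimeCourse:
    return TimeCourse(
        pair_label="toy",
        times=np.array([0.0, 1.0, 2.0]),
        antitoxin_values=np.array([0.0, 1.0, 2.0]),
        toxin_values=np.array([0.0, 1.0, 1.0]),
        scale_applied=1.0,
    )
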
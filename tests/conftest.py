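import numpy as np
import pytest

from splitbrood.pedigree import additive_relationship_matrix
from splitbrood.simulate import (
    DesignConfig,
    TrueParameters,
    correlation_to_covariance,
    simulate_breeding_design,
)

ENVS = ("ripe", "unripe", "none")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_truth(variances=(2.0, 1.0, 1.5), r=0.4, sigma2_e=3.0,
               env_means=(5.0, 4.0, 3.0), blocks=True):
    return TrueParameters(
        G=correlation_to_covariance(variances, r),
        sigma2_e=sigma2_e,
        env_means=env_means,
        block_effects={"d1": 0.0, "d2": 0.5, "d3": -0.5} if blocks else {"d1": 0.0},
    )


def small_dataset(seed=7, n_sires=8, dams=2, kids=4, truth=None):
    cfg = DesignConfig(
        n_sires=n_sires, dams_per_sire=dams, offspring_per_dam=kids,
        missing_cell_rate=0.0, seed=seed,
    )
    truth = truth or make_truth()
    ped, pheno = simulate_breeding_design(cfg, truth)
    A = additive_relationship_matrix(ped)
    return ped, pheno, A, truth


@pytest.fixture
def small_data():
    return small_dataset()
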
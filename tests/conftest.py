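import numpy as np
import pandas as pd
import pytest

from qsrrkit import PipelineConfig, SimulationConfig, generate


@pytest.fixture(scope="session")
def small_sim_config():
    """A fast two-pH benchmark used by the pipeline-level tests."""
    return SimulationConfig(
        n_compounds=40,
        n_descriptors=30,
        n_informative=4,
        ph_levels=(2.7, 5.0),
        block_size=5,
        intra_block_correlation=0.6,
        noise_sd=0.08,
        n_outliers=1,
        outlier_shift=10.0,
        low_retention_fraction=0.2,
        seed=5,
    )


@pytest.fixture(scope="session")
def small_pipeline_config(small_sim_config):
    return PipelineConfig(
        folds=5,
        n_test=6,
        cfs_max_features=8,
        rfe_subset_sizes=(4, 8, 16),
        grids={
            "MLR_CFS": {},
            "MLR_RFE": {},
            "SVR_CFS": {"C": [1.0, 4.0], "gamma_factor": [1.0], "epsilon": [0.1]},
            "SVR_RFE": {"C": [1.0, 4.0], "gamma_factor": [1.0], "epsilon": [0.1]},
            "Lasso": {"alpha": [0.01, 0.1]},
            "RF": {"n_estimators": [50], "mtry": ["sqrt"]},
            "GBM": {"n_estimators": [50], "max_depth": [2], "learning_rate": [0.1]},
        },
        stacking_oof_folds=5,
        stacking_repeats=1,
        seed=5,
        simulation=small_sim_config,
    )


@pytest.fixture(scope="session")
def small_dataset(small_sim_config):
    return generate(small_sim_config)


@pytest.fixture
def rng():
    return np.random.default_rng(123)


@pytest.fixture
def random_xy(rng):
    """A well-conditioned regression problem with named features."""
    X = pd.DataFrame(
        rng.standard_normal((60, 8)), columns=[f"f{i}" for i in range(8)]
    )
    y = X["f0"].to_numpy() * 2.0 - X["f3"].to_numpy() + rng.normal(0, 0.3, 60)
    return X, y
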
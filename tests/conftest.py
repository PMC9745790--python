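import numpy as np
import pandas as pd
import pytest

from nmix import (
    CountMatrix, NMixture, SimulationConfig, SiteCovariates, simulate_survey,
)

#: abundance truth used across tests: the canonical study-scale world
STATE_TRUTH = {"intercept": 0.95, "mixed": 0.33, "human_CR": 0.27,
               "vildist": 0.25, "sal.forest": 0.21}
DET_TRUTH = {"intercept": float(np.log(0.08 / 0.92)), "fruit_density": 0.27}
TOP_STATE = ("mixed", "human_CR", "vildist", "sal.forest")
TOP_DET = ("fruit_density",)


@pytest.fixture(scope="session")
def study_survey():
    """One simulated survey at the study design (73 sites, 1-4 replicates, 15 occasions)."""
    cfg = SimulationConfig(seed=11)
    counts, covs, truth = simulate_survey(cfg)
    return counts, covs, truth


@pytest.fixture(scope="session")
def top_fit(study_survey):
    counts, covs, _ = study_survey
    return NMixture("poisson", state_covariates=TOP_STATE,
                    det_covariates=TOP_DET).fit(counts, covs)


@pytest.fixture
def tiny_counts():
    """3 sites x (2 replicates x 2 occasions) with one missing cell."""
    y = np.array([
        [0.0, 1.0, 0.0, 0.0],
        [2.0, 0.0, np.nan, 1.0],
        [0.0, 0.0, 0.0, 0.0],
    ])
    return CountMatrix(y, ["A", "B", "C"], n_occasions=2, n_replicates=2)


@pytest.fixture
def raw_covs():
    rng = np.random.default_rng(5)
    df = pd.DataFrame(
        {"a": rng.normal(2, 1, 12), "b": rng.normal(-1, 3, 12),
         "c": rng.normal(0, 0.5, 12)},
        index=pd.Index([f"S{i}" for i in range(12)], name="site_id"),
    )
    return SiteCovariates(df)
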
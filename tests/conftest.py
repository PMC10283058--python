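import warnings

import numpy as np
import pytest

from uromics import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small five-class cohort shared across tests (read-only)."""
    cfg = CohortConfig(
        n_per_group={"HC": 25, "T2DM": 25, "GREY": 12, "EARLY_DKD": 25,
                     "OVERT_DKD": 18},
        effect_log2fc=0.8,
        seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def two_group_cohort():
    """Two-group cohort (no GREY/DKD classes) for pairwise-model tests."""
    cfg = CohortConfig(
        n_per_group={"T2DM": 40, "EARLY_DKD": 40},
        n_met_features=40, n_pep_features=40,
        n_stepwise_met=4, n_stepwise_pep=4,
        effect_log2fc=1.0, seed=5,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
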
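import numpy as np
import pandas as pd
import pytest

from neckteeth import (SimulationConfig, build_trait_table, generate_dataset,
                       score_table)

#: Clone-level covariance mirroring the reference study's modal estimate
#: (standardized-trait scale): modest variance in the maximum, more in
#: sensitivity, little in reactivity, negative maximum-sensitivity covariance.
MODAL_G = np.array([
    [0.18, -0.12, -0.001],
    [-0.12, 0.35, 0.03],
    [-0.001, 0.03, 0.02],
])


@pytest.fixture(scope="session")
def default_dataset():
    """One synthetic experiment under the reference design (12 clones,
    3 mothers, 5 replicates, 7 concentrations), fixed seed."""
    cfg = SimulationConfig(seed=7)
    induction, lifehistory, truth = generate_dataset(cfg)
    return cfg, induction, lifehistory, truth


@pytest.fixture(scope="session")
def default_traits(default_dataset):
    """Scored induction levels and fitted trait table for the default run."""
    _, induction, _, _ = default_dataset
    scored = score_table(induction, fixed_max=130)
    traits = build_trait_table(scored)
    return scored, traits


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
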
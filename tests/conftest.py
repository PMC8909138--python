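import numpy as np
import pytest

import cscmosaic as cm


@pytest.fixture(scope="session")
def sim_cohort():
    """Full-size synthetic cohort under default study conditions."""
    cfg = cm.SimConfig(seed=42)
    matrix, truth = cm.simulate_cells(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def overlap_fixture():
    return cm.printed_overlap_fixture()


@pytest.fixture()
def small_matrix():
    rng = np.random.default_rng(7)
    vals = rng.lognormal(0, 1, size=(30, 12))
    return cm.ExpressionMatrix(
        vals, [f"g{i:02d}" for i in range(30)], [f"c{i:02d}" for i in range(12)]
    )
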
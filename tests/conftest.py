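import numpy as np
import pytest

import pharmaconn as pc


@pytest.fixture(scope="session")
def space_small():
    return pc.make_space(120, n_networks=7, n_parcels=10, seed=1)


@pytest.fixture(scope="session")
def cohort_small(space_small):
    """Six-subject cohort on a small ring space (shared, read-only)."""
    cfg = pc.GeneratorConfig(
        n_subjects=6, n_gray=120, T=120, n_parcels=10, seed=7
    )
    design, runs, truth = pc.simulate_cohort(space_small, cfg)
    return cfg, design, runs, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
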
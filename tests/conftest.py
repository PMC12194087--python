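import numpy as np
import pandas as pd
import pytest

from greenrad.cohort import CohortSpec, simulate_cohort


@pytest.fixture
def small_cohort():
    """120 samples x 60 features, 8 informative in 2 blocks, binary target."""
    spec = CohortSpec(
        n_samples=120,
        n_features=60,
        n_blocks=15,
        block_rho=0.9,
        n_informative=8,
        effect_weights=(1.0,) * 8,
        noise_sd=0.5,
        informative_indices=tuple(range(8)),
        target_kind="binary_ratio",
        squash_max=1.0,
        seed=7,
    )
    table, target = simulate_cohort(spec)
    return spec, table, target


@pytest.fixture
def tiny_table():
    rng = np.random.default_rng(5)
    x = rng.normal(size=(30, 6))
    return pd.DataFrame(x, columns=[f"f{i}" for i in range(6)],
                        index=[f"S{i}" for i in range(30)])
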
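import numpy as np
import pandas as pd
import pytest

from txaging.simulate import CohortConfig, PlantedEffect, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """120 donors, one tissue, a sex shift and a latent batch factor."""
    cfg = CohortConfig(
        n_donors=120,
        n_genes=80,
        n_events=80,
        effect_blocks=[
            PlantedEffect(kind="sex_shift", magnitude=2.0, target_features=10)
        ],
        n_latent_factors=1,
        missing_psi_rate=0.02,
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def plain_frame():
    """Structure-free matrix for null checks: 60 features x 40 samples."""
    rng = np.random.default_rng(0)
    return pd.DataFrame(
        rng.normal(size=(60, 40)),
        index=[f"f{i}" for i in range(60)],
        columns=[f"s{i}" for i in range(40)],
    )
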
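import numpy as np
import pandas as pd
import pytest

from poolfilter import (
    build_pools,
    generate_dataset,
    standardize_rain,
    validate_observations,
)

#: seed of the reference synthetic dataset used across the suite
DATASET_SEED = 101


def make_toy_obs() -> pd.DataFrame:
    """Two hand-built sites small enough to verify every number by hand.

    Site A: regional {r1..r4}; vegetation {r1, r2 (sentinel 0.1)};
    seed bank {r1, x1} where x1 is a long-distance disperser absent from
    the regional survey; summer rain r1 (8 seedlings, 15/20 traps),
    winter rain r2 (2 seedlings, 20/20). Propagule pool {r1, r2, x1}.

    Site B: regional {r1, r2, r5}; vegetation {r1}; rain {r1} both
    seasons; bank {r2}. Propagule pool {r1, r2}.
    """
    rows = [
        ("A", "r1", "regional", 3, np.nan),
        ("A", "r2", "regional", 2, np.nan),
        ("A", "r3", "regional", 1, np.nan),
        ("A", "r4", "regional", 1, np.nan),
        ("A", "r1", "vegetation", 5, np.nan),
        ("A", "r2", "vegetation", 0.1, np.nan),
        ("A", "r1", "seed_bank", 2, np.nan),
        ("A", "x1", "seed_bank", 1, np.nan),
        ("A", "r1", "seed_rain_summer", 8, 15),
        ("A", "r2", "seed_rain_winter", 2, 20),
        ("B", "r1", "regional", 2, np.nan),
        ("B", "r2", "regional", 1, np.nan),
        ("B", "r5", "regional", 1, np.nan),
        ("B", "r1", "vegetation", 4, np.nan),
        ("B", "r1", "seed_rain_summer", 4, 20),
        ("B", "r1", "seed_rain_winter", 1, 20),
        ("B", "r2", "seed_bank", 3, np.nan),
    ]
    df = pd.DataFrame(
        rows, columns=["site_id", "species_id", "pool", "value", "n_samples_recovered"]
    )
    return validate_observations(df)


@pytest.fixture
def toy_obs() -> pd.DataFrame:
    return make_toy_obs()


@pytest.fixture(scope="session")
def default_dataset():
    """Reference synthetic dataset under the default study-design config."""
    return generate_dataset(seed=DATASET_SEED)


@pytest.fixture(scope="session")
def default_rain(default_dataset):
    return standardize_rain(default_dataset.observations)


@pytest.fixture(scope="session")
def default_pools(default_dataset, default_rain):
    return build_pools(default_dataset.observations, default_rain)
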
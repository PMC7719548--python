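import numpy as np
import pandas as pd
import pytest

from hzkit import ClineParams, GenotypeMatrix, default_scenario, simulate_zone


@pytest.fixture(scope="session")
def small_zone():
    """A down-scaled two-epoch zone shared by read-only tests."""
    sc = default_scenario(
        seed=11,
        site_positions=np.arange(1000.0, 1481.0, 40.0),  # 13 sites
        n_per_site=8,
        n_background_loci=300,
        missing_rate=0.05,
    )
    return simulate_zone(sc)


@pytest.fixture(scope="session")
def default_zone():
    """One realization of the full default study-condition scenario."""
    return simulate_zone(default_scenario(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def tiny_genotypes():
    """5 individuals x 4 loci with one missing call, for hand-worked checks."""
    d = np.array(
        [
            [0, 1, 2, 0],
            [0, 0, 2, 1],
            [1, 1, 1, 2],
            [2, 2, 0, np.nan],
            [2, 2, 0, 2],
        ],
        dtype=float,
    )
    return GenotypeMatrix(d, [f"ind{i}" for i in range(5)])
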
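import numpy as np
import pandas as pd
import pytest

from traitdiv import TraitTable, build_shared_space, simulate_study, simulate_traits
from traitdiv.traits import ACTIVITY_PERIODS, DIET_CATEGORIES, TRAIT_COLUMNS


def random_trait_frame(n_species: int, rng: np.random.Generator) -> pd.DataFrame:
    """Small random encoded trait table (valid per the coding contract)."""
    rows = {}
    for i in range(n_species):
        diet = (rng.random(5) < 0.4).astype(float)
        if diet.sum() == 0:
            diet[rng.integers(5)] = 1.0
        act = (rng.random(3) < 0.5).astype(float)
        if act.sum() == 0:
            act[rng.integers(3)] = 1.0
        rows[f"sp{i:02d}"] = {
            "mass": float(np.exp(rng.normal(1.5, 1.0))) + 1.0,
            **{f"diet_{c}": diet[j] for j, c in enumerate(DIET_CATEGORIES)},
            "social": float(rng.random() < 0.5),
            "substrate": float(rng.random() < 0.5),
            **{f"activity_{p}": act[j] for j, p in enumerate(ACTIVITY_PERIODS)},
            "litter_size": float(rng.integers(1, 6)),
        }
    df = pd.DataFrame.from_dict(rows, orient="index").loc[:, list(TRAIT_COLUMNS)]
    df.index.name = "species_id"
    return df


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210224)


@pytest.fixture(scope="session")
def small_traits():
    return TraitTable(random_trait_frame(8, np.random.default_rng(7)))


@pytest.fixture(scope="session")
def shared_space(small_traits):
    return build_shared_space(small_traits, m_fric=3)


@pytest.fixture(scope="session")
def study():
    """Default-condition synthetic study (15 sites), reused across tests."""
    return simulate_study(n_sites=15, n_species=80, seed=42)


@pytest.fixture(scope="session")
def traits80():
    return simulate_traits(80, seed=5)
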
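import numpy as np
import pytest

from factormap.task_env import Arena, MappingSpec, make_curriculum, make_mapping, make_schedule


@pytest.fixture(scope="session")
def grid_mapping() -> MappingSpec:
    """Identity grid mapping: color -> x, shape -> y, no shuffling."""
    return make_mapping("grid")


@pytest.fixture(scope="session")
def polar_mapping() -> MappingSpec:
    """Identity polar mapping: color -> ring, shape -> spoke, no rotation."""
    return make_mapping("polar")


@pytest.fixture(scope="session")
def arena() -> Arena:
    return Arena()


@pytest.fixture()
def aligned_schedule(grid_mapping):
    cur = make_curriculum(1, "grid", "aligned", 0, mapping=grid_mapping)
    return cur, make_schedule(cur, grid_mapping, 0)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
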
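import numpy as np
import pytest

from iapsync import CohortConfig, ParserConfig, RoIMap, ScreenGeometry
from iapsync.synthetic import default_roi_map


@pytest.fixture(scope="session")
def geometry() -> ScreenGeometry:
    return ScreenGeometry()


@pytest.fixture(scope="session")
def roi_map() -> RoIMap:
    return default_roi_map()


@pytest.fixture(scope="session")
def parser_config() -> ParserConfig:
    return ParserConfig()


@pytest.fixture()
def small_config() -> CohortConfig:
    """A cohort small enough for per-test stream synthesis."""
    return CohortConfig(seed=42, n_per_group=2, n_blocks=2, trials_per_block=8)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
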
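import numpy as np
import pandas as pd
import pytest

from weevilstats import SimulationConfig, datasets
from weevilstats.vocab import TREATMENTS


@pytest.fixture(scope="session")
def table2_records() -> pd.DataFrame:
    """Record-level expansion of the published treatment x outcome counts."""
    return datasets.destructive_records()


@pytest.fixture(scope="session")
def stage_records() -> pd.DataFrame:
    return datasets.stage_records()


@pytest.fixture()
def null_ratio_config():
    """Emergence config with no treatment effect (all rate ratios 1)."""
    def make(seed: int, n_blocks: int = 20, **kw) -> SimulationConfig:
        return SimulationConfig(
            seed=seed, n_blocks=n_blocks,
            rate_ratios={t: 1.0 for t in TREATMENTS}, **kw,
        )
    return make


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20221606)


def random_count_table(rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    """Random table with strictly positive margins."""
    while True:
        t = rng.poisson(6.0, size=(rows, cols))
        if t.sum(axis=0).all() and t.sum(axis=1).all():
            return t
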
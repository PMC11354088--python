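import numpy as np
import pandas as pd
import pytest

from resindex.preprocess import percentile_rank, standardize
from resindex.registry import (
    AreaMeta,
    AreaTable,
    IndicatorMeta,
    Registry,
    load_bundled_registry,
)
from resindex.synthetic import SyntheticConfig, generate


@pytest.fixture(scope="session")
def bundled_registry():
    return load_bundled_registry()


@pytest.fixture(scope="session")
def default_sim():
    """Default-config synthetic dataset (307 areas, 44 indicators, 5 factors)."""
    return generate(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def default_z(default_sim):
    return standardize(default_sim.table)


@pytest.fixture(scope="session")
def default_ranks(default_sim):
    return percentile_rank(default_sim.table)


def make_table(values: np.ndarray, directions=None, area_ids=None) -> AreaTable:
    """Small ad-hoc AreaTable for unit tests."""
    n, p = values.shape
    directions = directions or ["HIGH_GOOD"] * p
    indicators = tuple(
        IndicatorMeta(
            id=f"x{j + 1}",
            name=f"x{j + 1}",
            theme="Other",
            bric_domain="social",
            direction=directions[j],
        )
        for j in range(p)
    )
    registry = Registry(indicators)
    ids = area_ids or [f"A{i + 1}" for i in range(n)]
    areas = tuple(AreaMeta(area_id=aid) for aid in ids)
    frame = pd.DataFrame(values, index=ids, columns=registry.ids)
    return AreaTable(areas, frame, registry)
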
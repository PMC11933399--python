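import numpy as np
import pytest

from aquahazard.regions import ClimateZone, District, DistrictMap
from aquahazard.standards import load_standards
from shapely.geometry import box


@pytest.fixture(scope="session")
def who_standards():
    return load_standards("WHO_EPA")


@pytest.fixture(scope="session")
def who_by_param(who_standards):
    return {e.parameter: e for e in who_standards}


def make_strip_districts(n, width=40.0, height=60.0, populations=None):
    """n vertical-strip districts partitioning a width x height rectangle."""
    if populations is None:
        populations = [1000] * n
    step = width / n
    districts = [
        District(
            id=f"D{i + 1:02d}",
            polygon=box(i * step, 0.0, (i + 1) * step, height),
            climate_zone=ClimateZone.DRY,
            population=populations[i],
        )
        for i in range(n)
    ]
    return DistrictMap(districts=districts, bounds=(0.0, 0.0, width, height))


@pytest.fixture
def strip_districts():
    return make_strip_districts(2)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
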
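import pytest

from aquarisk import (
    default_registry,
    load_exposure_factors,
    load_reference_summary,
)
from aquarisk.occurrence import Measurement


@pytest.fixture(scope="session")
def exposure_table():
    return load_exposure_factors()


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def reference_summary():
    return load_reference_summary()


def make_measurement(
    city="Nanjing",
    season="dry",
    sample_id="D01",
    compound="caffeine",
    value=10.0,
    loq=1.0,
):
    return Measurement(
        city=city,
        season=season,
        sample_id=sample_id,
        compound=compound,
        value=value,
        loq=loq,
    )


@pytest.fixture
def toy_campaign():
    """Four samples, two compounds, known detection pattern.

    Sample D01: caffeine 10, atenolol ND    -> positive
    Sample D02: caffeine 60, atenolol 5     -> positive
    Sample W01: caffeine ND, atenolol ND    -> negative
    Sample W02: caffeine 2,  atenolol ND    -> positive
    """
    rows = [
        ("CityA", "dry", "D01", "caffeine", 10.0),
        ("CityA", "dry", "D01", "atenolol", None),
        ("CityA", "dry", "D02", "caffeine", 60.0),
        ("CityA", "dry", "D02", "atenolol", 5.0),
        ("CityB", "wet", "W01", "caffeine", None),
        ("CityB", "wet", "W01", "atenolol", None),
        ("CityB", "wet", "W02", "caffeine", 2.0),
        ("CityB", "wet", "W02", "atenolol", None),
    ]
    return [
        make_measurement(city=c, season=s, sample_id=i, compound=k, value=v)
        for c, s, i, k, v in rows
    ]
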
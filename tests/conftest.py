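import numpy as np
import pandas as pd
import pytest

from relolife import (
    AssignmentProfile,
    BackgroundSeries,
    CityYearTable,
    ModelConfig,
    PersonSpec,
    SynthParams,
    builtin_profiles,
    epa_cessation_weights,
    epa_inception_weights,
    synth_resources,
)


@pytest.fixture(scope="session")
def params():
    return SynthParams(seed=0)


@pytest.fixture(scope="session")
def resources(params):
    """Desk-default synthetic input bundle shared across the suite."""
    return synth_resources(params)


@pytest.fixture(scope="session")
def profiles():
    return builtin_profiles()


@pytest.fixture(scope="session")
def older_male():
    return PersonSpec.for_group("older", "male")


@pytest.fixture(scope="session")
def central_config():
    return ModelConfig()


@pytest.fixture(scope="session")
def epa_pair():
    return epa_inception_weights(), epa_cessation_weights()


@pytest.fixture
def tiny_city_table():
    return CityYearTable(
        pd.DataFrame(
            {
                "city_id": ["a", "a", "b"],
                "year": [2010, 2014, 2005],
                "pm25": [50.0, 40.0, 12.0],
            }
        )
    )


@pytest.fixture
def flat_background():
    """Constant 10 µg/m³ background over 2000–2020 with default backfills."""
    years = np.arange(2000, 2021)
    return BackgroundSeries(pd.Series(10.0, index=years))


@pytest.fixture
def empty_profile():
    return AssignmentProfile(label="home only")
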
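import datetime

import pytest

import csmp_survey as cs
from csmp_survey import datasets
from csmp_survey.synthetic import SurveyConfig, generate_survey

WORN_DATE_001 = datetime.date(2016, 9, 29)


@pytest.fixture(scope="session")
def worn_table():
    return datasets.load_worn_activities()


@pytest.fixture(scope="session")
def worn_table_raw():
    return datasets.load_worn_activities(raw=True)


@pytest.fixture(scope="session")
def table_2011():
    return datasets.load_activities_2011()


@pytest.fixture(scope="session")
def table_2011_raw():
    return datasets.load_activities_2011(raw=True)


@pytest.fixture(scope="session")
def efficiency_table():
    return datasets.load_pair_efficiencies()


@pytest.fixture(scope="session")
def fractions_table():
    return datasets.load_mask_fractions()


@pytest.fixture(scope="session")
def fractions_table_raw():
    return datasets.load_mask_fractions(raw=True)


@pytest.fixture(scope="session")
def default_survey():
    """One default-condition synthetic survey, shared across tests."""
    return generate_survey(SurveyConfig(seed=1))


@pytest.fixture
def mask_001_a137():
    """The first isolated particle's Cs-137 activity at its worn date."""
    return cs.Activity(nuclide=cs.CS137, reference_date=WORN_DATE_001, value=1.01, sigma=0.01)


@pytest.fixture
def mask_001_a134():
    return cs.Activity(nuclide=cs.CS134, reference_date=WORN_DATE_001, value=0.193, sigma=0.012)
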
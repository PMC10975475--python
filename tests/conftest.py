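import pandas as pd
import pytest
from hypothesis import settings

from pktranslate.core_io import DATASET_COLUMNS, StudyDataset
from pktranslate.physiology import get_species
from pktranslate.reference import XZP5610

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def rat():
    return get_species("rat")


@pytest.fixture(scope="session")
def dog():
    return get_species("dog")


@pytest.fixture(scope="session")
def human():
    return get_species("human")


@pytest.fixture(scope="session")
def drug():
    return XZP5610


def make_dataset(rows):
    """Rows of (subject, species, sex, group, route, dose, units, matrix,
    time, conc) -> StudyDataset."""
    return StudyDataset(records=pd.DataFrame(rows, columns=DATASET_COLUMNS))


@pytest.fixture
def tiny_iv_dataset():
    rows = [("S1", "rat", "M", "G1", "iv_bolus", 1.0, "mg/kg", "plasma",
             t, 100.0 * 2.718281828 ** (-0.5 * t))
            for t in (0.25, 0.5, 1, 2, 4, 8, 12, 24)]
    return make_dataset(rows)
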
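import pandas as pd
import pytest

from nucleoquant.panel import load_reference_panel, panel_by_code
from nucleoquant.reference import (
    load_reference_calibration,
    load_reference_isr_differences,
    load_reference_qc_performance,
)


@pytest.fixture(scope="session")
def panel():
    return load_reference_panel()


@pytest.fixture(scope="session")
def panel_map():
    return panel_by_code()


@pytest.fixture(scope="session")
def calibration_ref() -> pd.DataFrame:
    return load_reference_calibration()


@pytest.fixture(scope="session")
def qc_ref() -> pd.DataFrame:
    return load_reference_qc_performance()


@pytest.fixture(scope="session")
def isr_ref() -> pd.DataFrame:
    return load_reference_isr_differences()
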
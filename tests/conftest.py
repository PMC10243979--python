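from pathlib import Path

import pandas as pd
import pytest

from xrflabel import BeamConfig, DetectorModel, LineCatalogue

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def catalogue() -> LineCatalogue:
    return LineCatalogue.default()


@pytest.fixture(scope="session")
def catalogue_frame() -> pd.DataFrame:
    """Raw catalogue table, for independent-oracle recomputations."""
    return LineCatalogue.default().to_frame()


@pytest.fixture(scope="session")
def reference_lines() -> pd.DataFrame:
    """Hand-entered published line energies (independent tabulation)."""
    return pd.read_csv(DATA_DIR / "reference_lines.csv")


@pytest.fixture
def detector() -> DetectorModel:
    return DetectorModel.default()


@pytest.fixture
def beam77() -> BeamConfig:
    return BeamConfig(excitation_keV=7.7)


@pytest.fixture
def beam57() -> BeamConfig:
    return BeamConfig(excitation_keV=5.7)
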
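import numpy as np
import pandas as pd
import pytest

from overflux.core import MetaboliteRegistry
from overflux.fba import default_model


@pytest.fixture(scope="session")
def registry():
    return MetaboliteRegistry.default()


@pytest.fixture(scope="session")
def model():
    return default_model()


@pytest.fixture
def profile_table(tmp_path):
    """Write a minimal well-formed concentration table and return its path."""

    def _write(rows, name="profiles.csv"):
        path = tmp_path / name
        pd.DataFrame(rows).to_csv(path, index=False)
        return path

    return _write
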
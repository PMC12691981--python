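import numpy as np
import pandas as pd
import pytest

from molsim import BlobSpec, DescriptorTable, make_blob_table


@pytest.fixture
def small_table() -> DescriptorTable:
    """3 molecules × 5 descriptors, mixed blocks, hand-written values."""
    data = pd.DataFrame(
        {
            "MW": [300.0, 350.0, 280.0],
            "TPSA": [40.0, 60.0, 55.0],
            "BBB": [1.0, 0.0, 1.0],
            "HOMO": [-6.1, -5.8, -6.4],
            "LUMO": [-1.2, -0.9, -1.5],
        },
        index=["DNP", "GNT", "THA"],
    )
    blocks = pd.Series(
        {"MW": "ADMET", "TPSA": "ADMET", "BBB": "ADMET", "HOMO": "ES", "LUMO": "ES"}
    )
    labels = pd.Series(
        {"DNP": "classical", "GNT": "classical", "THA": "classical"}, dtype=object
    )
    return DescriptorTable(data, blocks, labels)


@pytest.fixture
def blob_table() -> DescriptorTable:
    """Default 30-molecule, 5-class synthetic panel."""
    return make_blob_table(BlobSpec(seed=7))


@pytest.fixture
def separated_blob() -> DescriptorTable:
    """Well-separated panel (10σ between class centers)."""
    return make_blob_table(BlobSpec(separation=10.0, seed=7))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
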
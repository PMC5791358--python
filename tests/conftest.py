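import numpy as np
import pandas as pd
import pytest

from filterforensics import FeatureTable, Metadata


@pytest.fixture
def tiny_table():
    """2 samples x 3 OTUs with hand-checkable counts."""
    return FeatureTable(
        ["S1", "S2"],
        ["OTU_A", "OTU_B", "OTU_C"],
        np.array([[1.0, 0.0, 3.0], [2.0, 5.0, 3.0]]),
    )


@pytest.fixture
def three_method_metadata():
    def build(sample_ids, methods):
        frame = pd.DataFrame(
            {
                "sample_id": sample_ids,
                "method": methods,
                "household": "houseA",
                "assay": "bacteria_16S",
                "sampled_area_cm2": 31.25,
                "dust_mass_mg": np.nan,
            }
        ).set_index("sample_id")
        return Metadata(frame)

    return build


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)
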
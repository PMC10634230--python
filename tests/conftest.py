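import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)


@pytest.fixture
def small_counts():
    """4 genes x 6 samples with a clear female-biased gene."""
    counts = pd.DataFrame(
        {
            "F1": [100, 50, 4000, 30],
            "F2": [120, 60, 3800, 28],
            "F3": [90, 55, 4200, 35],
            "M1": [110, 52, 40, 30],
            "M2": [95, 58, 50, 32],
            "M3": [105, 49, 30, 29],
        },
        index=pd.Index(["G1", "G2", "BIAS", "G4"], name="gene_symbol"),
    )
    meta = pd.DataFrame(
        {
            "sample_id": counts.columns,
            "sex": ["female"] * 3 + ["male"] * 3,
            "tissue": ["blood"] * 6,
        }
    ).set_index("sample_id")
    lengths = pd.Series([1000.0, 500.0, 2000.0, 800.0], index=counts.index)
    return counts, meta, lengths
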
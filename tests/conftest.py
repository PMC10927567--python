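import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

import matplotlib

matplotlib.use("Agg")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_quant_table():
    """A tiny complete ProteinQuantTable with 5v5 replicates + 3 totals."""
    from trexkit.quant_io import ProteinQuantTable

    rng = np.random.default_rng(7)
    cols = [f"plus_{i}" for i in range(1, 6)] + \
           [f"minus_{i}" for i in range(1, 6)] + \
           [f"total_{i}" for i in range(1, 4)]
    groups = ["plus_rnaseh"] * 5 + ["minus_rnaseh"] * 5 + ["total"] * 3
    reps = list(range(1, 6)) * 2 + list(range(1, 4))
    intensity = pd.DataFrame(
        2.0 ** rng.normal(25, 2, size=(20, 13)),
        index=[f"P{i:03d}" for i in range(20)], columns=cols)
    samples = pd.DataFrame({"group": groups, "replicate": reps},
                           index=pd.Index(cols, name="sample_id"))
    return ProteinQuantTable(intensity=intensity, ibaq=intensity / 10,
                             samples=samples)
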
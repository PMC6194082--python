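import numpy as np
import pandas as pd
import pytest

from dnasip.community import OtuTable
from dnasip.simulate import GradientConfig, make_community


@pytest.fixture
def clean_gradient_config():
    """Gradient without measurement noise or diffusive smear: bands only."""
    return GradientConfig(dna_noise_cv=0.0, background_smear=0.0)


@pytest.fixture
def community():
    return make_community(n_taxa=50, n_rapid=3, n_slow=5, seed=7)


@pytest.fixture
def small_table():
    counts = pd.DataFrame(
        [[30, 10, 0, 5], [5, 25, 10, 5], [0, 0, 40, 5]],
        index=["s1", "s2", "s3"],
        columns=[f"OTU{i}" for i in range(1, 5)],
    )
    meta = pd.DataFrame(
        {"role": ["H", "L", "in-situ"], "treatment": "labeled", "timepoint_days": 1.0},
        index=counts.index,
    )
    return OtuTable(counts=counts, sample_meta=meta)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
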
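import numpy as np
import pandas as pd
import pytest

from hepamark import normalization as nm
from hepamark import synthetic_data as sd
from hepamark.table_io import MARKER_GENES


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def study_counts():
    """A 15-sample, 3-group count table (cont / AAF-like / CRE-like)."""
    return sd.simulate_counts(sd.default_study_config(seed=7))


@pytest.fixture(scope="session")
def study_ratio(study_counts):
    return nm.normalize_pipeline(study_counts)


@pytest.fixture(scope="session")
def reference_panel():
    return sd.simulate_reference_panel(sd.PanelSimulationConfig(seed=11))


def random_profile(rng, label="p"):
    values = pd.Series(rng.normal(0, 2, size=len(MARKER_GENES)),
                       index=list(MARKER_GENES))
    return nm.Log2RatioProfile(values=values, label=label)
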
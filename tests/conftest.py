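import numpy as np
import pytest
from hypothesis import settings

from silvicarbon.data_io import ObservationRecord

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def make_record():
    """Factory for valid observation records with overridable fields."""

    def _make(**overrides) -> ObservationRecord:
        base = dict(
            study_id="study001",
            site_id="site1",
            treatment="interplant",
            mean_treat=60.0,
            mean_ctrl=50.0,
            sd_treat=6.0,
            sd_ctrl=5.0,
            n_treat=4,
            n_ctrl=4,
        )
        base.update(overrides)
        return ObservationRecord(**base)

    return _make


@pytest.fixture
def toy_effects():
    """Tiny effects table with nested publications, as a DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        {
            "lnrr": [0.2, 0.5, 0.3, 0.9, 0.1, 0.6],
            "variance": [0.04, 0.02, 0.05, 0.03, 0.06, 0.02],
            "study_id": ["a", "a", "b", "b", "c", "d"],
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
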
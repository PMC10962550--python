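import numpy as np
import pytest

from abnmap import SyntheticSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    """Scaled-down study conditions for fast unit tests."""
    return SyntheticSpec(
        seed=7,
        n_normative_subjects=40,
        n_patients_good=3,
        n_patients_poor=3,
        n_regions=24,
        n_regions_covered_range=(12, 18),
        n_resected_range=(3, 5),
        recording_hours=1.0,
    )
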
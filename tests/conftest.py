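import numpy as np
import pytest

from adneuro.synthetic import SyntheticCohortSpec, EEGParams

# compact montage: all frontal pairs plus a few posterior sites, enough
# for GFP/PI while keeping filtering cheap in tests
SMALL_CHANNELS = ["Fp1", "Fp2", "AF3", "AF4", "F3", "F4", "F7", "F8",
                  "Fz", "Cz", "Pz", "O1"]


@pytest.fixture
def small_spec() -> SyntheticCohortSpec:
    """Short-duration cohort spec for fast stream-level tests."""
    return SyntheticCohortSpec(
        n_subjects=2, n_ads=2, ad_duration_s=10.0, baseline_duration_s=15.0,
        eeg=EEGParams(channels=list(SMALL_CHANNELS)), seed=123)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
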
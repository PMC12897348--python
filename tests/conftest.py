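"""Shared fixtures for the test suite."""

import warnings

import numpy as np
import pytest

from tbscreen.cohort import (
    CohortSpec,
    cohort_manifest,
    generate_cohort,
    generate_feature_cohort,
    synth_breath_recording,
)

# The OOB-coverage advisory fires by design with small bags; keep test
# output readable without changing behaviour.
warnings.filterwarnings("ignore", message=".*lack OOB members.*")

FAST_SIZES = {"non": 45, "mild": 21, "moderate": 30, "severe": 24}


@pytest.fixture(scope="session")
def default_manifest():
    """Anthropometric manifest of the full default cohort (no audio)."""
    subjects = generate_cohort(CohortSpec(with_recordings=False, seed=3))
    return cohort_manifest(subjects)


@pytest.fixture(scope="session")
def feature_cohort():
    """Reduced feature-level cohort (n=120) shared by tabular tests."""
    spec = CohortSpec(class_sizes=dict(FAST_SIZES), acoustic_effect_size=1.0,
                      with_recordings=False, seed=7)
    return generate_feature_cohort(spec)


@pytest.fixture(scope="session")
def one_recording():
    """A single synthetic nose recording (non class, default effect)."""
    return synth_breath_recording("non", "nose", 1.0, seed=0)


@pytest.fixture()
def rng():
    # function-scoped: every test sees the same deterministic stream
    # regardless of which other tests ran before it
    return np.random.default_rng(12345)
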
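import numpy as np
import pytest

from gaitfive.pipeline import prepare_sequence
from gaitfive.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def walking_sequence():
    """One 75-frame synthetic walking sequence with realistic kinematics."""
    cfg = SyntheticConfig(n_subjects=1, seed=7)
    seqs, _, _ = generate_cohort(cfg)
    return seqs[0]


@pytest.fixture(scope="session")
def prepared_sequence(walking_sequence):
    """The walking sequence translated to the MidHip origin and smoothed."""
    return prepare_sequence(walking_sequence)


@pytest.fixture(scope="session")
def small_cohort():
    """A 20-subject cohort with strong trait effects, for modeling tests."""
    cfg = SyntheticConfig(n_subjects=20, seed=3)
    return generate_cohort(cfg)
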
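import numpy as np
import pytest

from peridep.synthetic_cohort import SyntheticConfig, generate_cohort
from peridep.text_features import ThemeLexicon, ValenceLexicon


@pytest.fixture(scope="session")
def valence():
    return ValenceLexicon.default()


@pytest.fixture(scope="session")
def themes():
    return ThemeLexicon.default()


@pytest.fixture(scope="session")
def small_cohort():
    """A small signal-bearing cohort shared by pipeline-level tests."""
    return generate_cohort(
        SyntheticConfig(n_participants=150, beta_mood=1.2, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
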
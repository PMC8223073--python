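import numpy as np
import pytest

from weightgrade import simulate
from weightgrade.composition import profile_cohort
from weightgrade.status import CutoffTable


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_cohort():
    """Calibrated synthetic cohort, 400 players per age block."""
    return simulate.generate(simulate.default_spec(seed=7).with_n(400))


@pytest.fixture(scope="session")
def small_profile(small_cohort):
    return profile_cohort(small_cohort)


@pytest.fixture()
def toy_cutoffs():
    """Two-row cut-off table used by every status test (never the shipped grid)."""
    return CutoffTable(ages=[10.0, 10.5], ow_cut=[20.0, 21.0], ob_cut=[25.0, 26.0])
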
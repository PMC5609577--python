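import numpy as np
import pytest

from lipopls.chemometrics import PanelConfig, calibrate_panel
from lipopls.simulate import simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """24-sample low-HDL cohort for cheap structural checks."""
    return simulate_cohort("low_hdl_cm", 24, seed=7)


@pytest.fixture(scope="session")
def default_panel():
    """Full 48-model calibration on the default 122-sample cohort.

    A single permutation keeps the run fast; permutation count does not
    affect splits, component selection or prediction quality.
    """
    cohort = simulate_cohort("low_hdl_cm", 122, seed=1)
    panel = calibrate_panel(cohort.spectra, cohort.truth,
                            PanelConfig(n_permutations=1, seed=1))
    return cohort, panel


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
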
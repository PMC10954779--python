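import math
import warnings

import numpy as np
import pytest

import angiorad as ar
from angiorad.synthetic import BolusModel, GammaBolus

warnings.filterwarnings("ignore", category=FutureWarning)

SMALL_ACQ = ar.AcquisitionSpec(rows=64, cols=64)


@pytest.fixture(scope="session")
def small_acq():
    return SMALL_ACQ


@pytest.fixture(scope="session")
def clean_sac_bolus():
    """Sac-only bolus (no background/artery contrast, no noise)."""
    return BolusModel(background=GammaBolus(0.0, 0.9, 2.0, 0.6),
                      artery=GammaBolus(0.0, 0.8, 1.5, 0.4),
                      sac=GammaBolus(300.0, 1.0, 2.0, 0.8),
                      noise_sd=0.0)


@pytest.fixture(scope="session")
def sac_spec():
    return ar.CaseSpec("PIU_000", "PIU", 50.0, "M", 18.0, "ICA", "single",
                       sac_center=(32.0, 32.0), sac_semi_axes_px=(10.0, 7.0),
                       sac_orientation_rad=0.3)


@pytest.fixture(scope="session")
def default_case(small_acq, sac_spec):
    """One rendered synthetic case with noise, at desk scale."""
    return ar.generate_case(sac_spec, small_acq, seed=11)


@pytest.fixture(scope="session")
def default_mapset(default_case):
    union = default_case.mask_rater1 | default_case.mask_rater2
    return ar.build_maps(default_case.frames, union)


def simplified_gamma(t, ymax, t0, tmax, alpha):
    """Reference evaluation of the peak-referenced gamma variate."""
    t = np.asarray(t, float)
    u = (t - t0) / (tmax - t0)
    with np.errstate(invalid="ignore"):
        y = ymax * np.where(u > 0, u, 1.0) ** alpha * np.exp(alpha * (1 - u))
    return np.where(u > 0, y, 0.0)
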
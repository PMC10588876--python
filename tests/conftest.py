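import numpy as np
import pytest

from ec50shrink import LL4Params, predict_ll4
from ec50shrink.dose_response import VPA_DESIGN


@pytest.fixture(scope="session")
def vpa_x():
    """The 27-observation concentration vector of the case-study design."""
    return VPA_DESIGN.expand()


@pytest.fixture(scope="session")
def well_identified_truth():
    """A steep, mid-range truth curve: effect 2 log2 units, EC50 at 450 uM."""
    return LL4Params(b=1.5, c=6.0, d=8.0, e_tilde=float(np.log(450.0)))


@pytest.fixture(scope="session")
def noisy_fixture(vpa_x, well_identified_truth):
    """One seeded noisy dataset from the well-identified truth (sd 0.1)."""
    rng = np.random.default_rng(20231020)
    y = predict_ll4(well_identified_truth, vpa_x) + rng.normal(0, 0.1, vpa_x.size)
    return vpa_x, y
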
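import numpy as np
import pytest

from meandergrid import build_standard_curve


@pytest.fixture(scope="session")
def default_curve():
    """The default standard curve (8 c.s.d. values x 10 reps, 400x400 walks).

    Built once per session; several calibration and field tests share it.
    """
    return build_standard_curve(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
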
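import numpy as np
import pytest

from pmstates import (
    HopfParams,
    RegionalTimeSeries,
    generate_connectome,
)


@pytest.fixture(scope="session")
def small_connectome():
    return generate_connectome(10, n_modules=2, homotopic_strength=1.0, seed=1)


@pytest.fixture(scope="session")
def uncoupled_params():
    """Single noise-free node on its limit cycle at 0.05 Hz."""
    return HopfParams(
        a=np.array([0.04]),
        omega=np.array([2 * np.pi * 0.05]),
        G=0.0,
        beta=0.0,
        transient_s=150.0,
    )


@pytest.fixture()
def sinusoid_ts():
    """Two-region 0.05 Hz sinusoid block, 600 samples at TR = 2 s."""
    t = np.arange(600) * 2.0
    x = np.vstack([np.cos(2 * np.pi * 0.05 * t), np.sin(2 * np.pi * 0.05 * t)])
    return RegionalTimeSeries(x, tr_s=2.0, subject_id="sub-fix")
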
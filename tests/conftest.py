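import numpy as np
import pytest

import renalmri as rm
from renalmri.phantom import RegionTruth


@pytest.fixture(scope="session")
def kidney_truth():
    """Baseline whole-kidney IVIM ground truth (uniform over the kidney)."""
    return rm.IvimParams(s0=1000.0, f=0.269, d=1.245e-3, d_star=4.0e-2)


@pytest.fixture(scope="session")
def uniform_phantom(kidney_truth):
    """Phantom with one uniform ground truth across the whole kidney, SNR 20."""
    spec = rm.PhantomSpec(
        region_params={
            "whole_kidney": RegionTruth(kidney_truth, rm.T2StarParams(s0=1000.0, t2_star=32.8))
        }
    )
    return rm.make_phantom(spec)


@pytest.fixture(scope="session")
def regional_phantom():
    """Phantom with distinct cortex/medulla ground truths (the default spec)."""
    return rm.make_phantom(rm.PhantomSpec())


@pytest.fixture
def noiseless_ivim_curve(kidney_truth):
    signal = rm.ivim_signal(kidney_truth, np.asarray(rm.DWI_B_VALUES))
    return rm.DecayCurve.dwi(signal)
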
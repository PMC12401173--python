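import numpy as np
import pytest

from spermfx.synthetic_data import (
    CalTraceTruth,
    P4TraceTruth,
    calibration_trace_spec,
    make_calibration_trace,
    make_p4_trace,
    p4_trace_spec,
)


@pytest.fixture
def cal_truth():
    return CalTraceTruth(resting_em=-50.0, fluorescence_per_mv=1.0)


@pytest.fixture
def noiseless_cal_trace(cal_truth):
    return make_calibration_trace(cal_truth, calibration_trace_spec(cal_truth))


@pytest.fixture
def p4_truth():
    # ΔP4/τ-up/τ-down at the normozoospermic DGC medians
    return P4TraceTruth(
        delta_p4=1.9, tau_up=3.3, tau_down=17.7,
        iono_level=260.0, mn_level=40.0,
        p4_time=10.0, iono_time=80.0, mn_time=90.0,
    )


@pytest.fixture
def noiseless_p4_trace(p4_truth):
    return make_p4_trace(p4_truth, p4_trace_spec(p4_truth))


@pytest.fixture
def rng():
    return np.random.default_rng(20250714)
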
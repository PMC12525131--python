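import numpy as np
import pytest

import pilotle as p


@pytest.fixture
def default_params() -> p.PKParams:
    return p.PKParams(tau_abs=6.9, tau_decay=100.0, alpha=1.0)


@pytest.fixture
def single_dose_schedule() -> p.DoseSchedule:
    return p.DoseSchedule([p.DoseEvent(time=0.0, dose=166.0)])


def bateman_grid_oracle(tau_abs: float, tau_decay: float, t_end: float = 2000.0,
                        dt: float = 0.001):
    """Independent dense-grid evaluation of the unnormalized two-exponential
    difference, used as the oracle for peak time and unit-peak values."""
    t = np.arange(dt, t_end, dt)
    raw = np.exp(-t / tau_decay) - np.exp(-t / tau_abs)
    if raw.max() < -raw.min():  # tau_abs > tau_decay flips the sign
        raw = -raw
    i = int(np.argmax(raw))
    return t, raw / raw[i], float(t[i])
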
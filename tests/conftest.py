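import numpy as np
import pytest

import headpdr as hp
from headpdr.steplength import calibrate


@pytest.fixture(scope="session")
def noiseless():
    return hp.SensorErrorModel.noiseless()


@pytest.fixture(scope="session")
def calibrated_weinberg(noiseless):
    """Weinberg k fitted on a noise-free straight calibration walk."""
    seq, truth = hp.simulate_walk(hp.straight_line(20.0), noiseless)
    steps = hp.collect_calibration_steps(seq, real_length=truth.total_length)
    return calibrate("weinberg", steps)


@pytest.fixture(scope="session")
def calibrated_zhu():
    """Zhu hybrid coefficients from varied-cadence calibration walks."""
    pairs = []
    for f, l, amp in [(1.6, 0.45, 1.6), (1.8, 0.5, 2.0), (2.0, 0.55, 2.5)]:
        sc = hp.straight_line(18.0, step_length=l, step_frequency=f, osc_amplitude=amp)
        seq, _ = hp.simulate_walk(sc, hp.SensorErrorModel(seed=99))
        pairs += hp.collect_calibration_steps(seq, step_length=l)
    return calibrate("zhu", pairs)


@pytest.fixture(scope="session")
def rectangle_noise_free(noiseless):
    """One noise-free benchmark rectangle walk with its ground truth."""
    return hp.simulate_walk(hp.default_rectangle(), noiseless)


def random_unit_quaternion(rng):
    q = rng.normal(size=4)
    return q / np.linalg.norm(q)
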
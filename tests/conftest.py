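import numpy as np
import pytest

from ames import (
    FilterSpec,
    LearningCurve,
    SimulationParams,
    complicated_template,
    simple_template,
)

FS = 80.3


@pytest.fixture(scope="session")
def template_11():
    return simple_template()


@pytest.fixture(scope="session")
def template_21():
    return complicated_template()


@pytest.fixture(scope="session")
def filter_spec():
    return FilterSpec()


def zero_params() -> SimulationParams:
    """Noise-free, distortion-free simulation parameters."""
    return SimulationParams(
        magnitude=LearningCurve(0.0, 0.0, 1.0),
        shape=LearningCurve(0.0, 0.0, 1.0),
        drift_amp_mm=0.0,
        noise_amp_mm=0.0,
        participant_sd=0.0,
    )


def flat_params(magnitude=0.0, shape=0.0, drift=0.3, noise=0.1, participant_sd=0.0):
    """Constant error scales across phases."""
    return SimulationParams(
        magnitude=LearningCurve(magnitude, magnitude, 1.0),
        shape=LearningCurve(shape, shape, 1.0),
        drift_amp_mm=drift,
        noise_amp_mm=noise,
        participant_sd=participant_sd,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
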
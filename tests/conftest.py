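import numpy as np
import pytest

from adlsense.io_streams import SensorSample, SensorSeries
from adlsense.synthetic import daily_routine_script, generate_session


def series_from_array(t, values, modality="accelerometer", rate=None, duration=None):
    """Build a SensorSeries from parallel arrays."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] != len(t):
        values = values.T
    samples = [SensorSample(float(ti), tuple(row)) for ti, row in zip(t, values)]
    return SensorSeries(modality=modality, samples=samples, nominal_rate=rate, duration=duration)


@pytest.fixture(scope="session")
def routine_session():
    """One noiseless scripted session reused by read-only tests."""
    return generate_session(daily_routine_script(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
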
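import numpy as np
import pytest

from fwave.pipeline import make_fixtures
from fwave.synthetic import WaveformParams
from fwave.types import Nerve


@pytest.fixture(scope="session")
def fixture_sessions():
    """Deterministic miniature cohort: 6 ALS + 6 control sessions covering
    all four nerves and missing-nerve protocols."""
    return make_fixtures(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def ulnar_params():
    """Noiseless single-session ulnar waveform parameters."""
    return WaveformParams(
        nerve=Nerve.ULNAR, m_onset_latency=3.5, m_amplitude=8.0, m_duration=9.0,
        f_present=True, f_onset_latency=28.0, f_amplitude=0.9, f_n_phases=3,
        noise_sd=0.0)
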
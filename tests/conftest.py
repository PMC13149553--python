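import numpy as np
import pytest

from speedcode.config import AnalysisConfig
from speedcode.session import Session, SpeedTrace, SpikeTrain, StimulusEvent, StimulusSchedule
from speedcode.synthetic import (
    BoutSchedule,
    EncodingParams,
    generate_bouts_and_speed,
    make_r_neuron_session,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def flat_trace():
    """60 s of zero speed at 100 Hz."""
    return SpeedTrace(sampling_rate=100.0, samples=np.zeros(6000))


@pytest.fixture
def one_bout_trace():
    """A single 5 s bout at 20 cm/s starting at t = 10 s (noiseless)."""
    sched = BoutSchedule(bouts=[(10.0, 5.0, 20.0)])
    return generate_bouts_and_speed(sched, 100.0, speed_noise_sd=0.0, seed=0, duration=60.0)


@pytest.fixture
def toy_session(one_bout_trace):
    spikes = SpikeTrain("a", np.array([0.5, 11.0, 12.0, 13.0]), 60.0)
    stim = StimulusSchedule([StimulusEvent("sound", 2.0, 1.0)])
    return Session(spike_trains=[spikes], speed=one_bout_trace, stimuli=stim)


@pytest.fixture(scope="session")
def default_r_session():
    """One synthetic running-related neuron at the default conditions."""
    return make_r_neuron_session(EncodingParams(lag=2.0), seed=7)


@pytest.fixture
def config():
    return AnalysisConfig(n_permutations=100, rng_seed=0)
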
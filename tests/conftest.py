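import numpy as np
import pytest

from ecogpipe import COMPARTMENTS, PipelineConfig, SynthConfig, generate_recording


@pytest.fixture(scope="session")
def small_recording():
    """One channel per compartment, 30 s at 500 Hz, fixed seed."""
    cfg = SynthConfig(sampling_rate=500.0, duration=30.0,
                      channels_per_compartment={k: 1 for k in COMPARTMENTS},
                      seed=7)
    return generate_recording(cfg)


@pytest.fixture(scope="session")
def cohort_recording():
    """Six channels per compartment, 30 s at 500 Hz (used by several stages)."""
    cfg = SynthConfig(sampling_rate=500.0, duration=30.0,
                      channels_per_compartment={k: 6 for k in COMPARTMENTS},
                      seed=11)
    return generate_recording(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
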
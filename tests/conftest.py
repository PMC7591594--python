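import warnings

import numpy as np
import pytest

import respchron as rc


@pytest.fixture(scope="session")
def identity_calib():
    """Calibration with REL = 0 everywhere and SV = 1 (features pass through)."""
    return rc.Calibration(sv=1.0, rel_times=np.array([0.0]),
                          rel_values=np.array([0.0]))


@pytest.fixture(scope="session")
def short_sim():
    """A 5-minute three-party simulation with its pipeline result."""
    traces, speech, laughter, truth = rc.simulate_conversation(
        rc.SimConfig(duration_s=300), seed=11)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = rc.analyze_conversation(traces, speech, laughter)
    return traces, speech, laughter, truth, result


@pytest.fixture(scope="session")
def noiseless_sim():
    """A noise-free 5-minute simulation with its pipeline result."""
    traces, speech, laughter, truth = rc.simulate_conversation(
        rc.SimConfig(duration_s=300, noise_sd=0.0), seed=11)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = rc.analyze_conversation(traces, speech, laughter)
    return traces, speech, laughter, truth, result
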
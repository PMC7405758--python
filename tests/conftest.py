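import pytest

from pursuitflash import synthetic as syn
from pursuitflash.core import Condition


@pytest.fixture(scope="session")
def clean_observer():
    """Observer with no trace artifacts: deterministic gaze, no saccades/blinks."""
    return syn.make_observer(
        0,
        {
            "trace_noise_deg": 0.0,
            "saccade_rate_hz": 0.0,
            "blink_prob": 0.0,
            "gain_sd": 0.0,
            "pursuit_gain": 1.0,
        },
    )


@pytest.fixture(scope="session")
def pursuit_condition():
    return Condition(
        task="pursuit_relative",
        phase="fine2",
        hemifield="right",
        pursuit_direction="rightward",
        placement="ahead",
        soa_ms=200,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete synthetic experiment (2 subjects), with QC flags."""
    trials, traces, manifest = syn.generate_dataset(
        n_subjects=2,
        counts={
            "pursuit_relative": 20,
            "fixation_relative": 24,
            "pursuit_absolute": 10,
            "coarse_per_offset": 1,
        },
        seed=42,
    )
    return trials, traces, manifest
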
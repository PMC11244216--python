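from pathlib import Path

import pytest

from ecgflow import SynthConfig, generate_ecg

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def excerpt_path() -> Path:
    """Ten-beat fiducial-table excerpt in the published CSV schema."""
    return DATA_DIR / "fiducials_excerpt.csv"


@pytest.fixture(scope="session")
def clean_signal_truth():
    """Noise-free 60 bpm / 10 s / 360 Hz trace with its ground truth."""
    return generate_ecg(SynthConfig(seed=1).clean())


@pytest.fixture(scope="session")
def noisy_signal_truth():
    """Default-noise 60 bpm trace with its ground truth."""
    return generate_ecg(SynthConfig(seed=1))
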
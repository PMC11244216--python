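"""Core signal container used throughout the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ECGSignal:
    """A single-lead ECG trace: a 1-D amplitude series plus its sampling frequency.

    Amplitudes are in arbitrary units (the device's digitizer scale is not
    assumed); ``fs`` is in Hz. The container is deliberately thin — all
    processing stages accept and return ``ECGSignal`` so that the sampling
    frequency travels with the samples.
    """

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("ECGSignal requires a 1-D sample array")
        if not self.fs > 0:
            raise ValueError(f"sampling frequency must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("ECGSignal samples must be finite")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        """Trace length in seconds."""
        return len(self.samples) / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(len(self.samples)) / self.fs

    def replace(self, samples: np.ndarray) -> "ECGSignal":
        """Return a new signal with the same fs and different samples."""
        return ECGSignal(samples=np.asarray(samples, dtype=float), fs=self.fs)

    def __neg__(self) -> "ECGSignal":
        return self.replace(-self.samples)
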
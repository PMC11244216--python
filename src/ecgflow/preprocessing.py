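"""Software noise-suppression stages for single-lead ECG.

Three stages mirror the usual wearable-ECG software chain:

* a **median filter** for impulsive artifacts (isolated spike samples),
* a zero-phase **Butterworth band-pass** removing baseline wander below the
  low cut and high-frequency noise above the high cut,
* a narrow **notch** at the mains frequency (50 or 60 Hz).

The band-pass magnitude model ``1 / (1 + (f/fc)^(2n))`` — value 1 at DC,
exactly 0.5 at the cut-off, monotone decreasing, steeper with order ``n`` —
is exposed as :func:`response_magnitude` for analytic checks; the realizable
digital filter is a forward-backward Butterworth so that fiducial timing is
not skewed by phase lag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage
import scipy.signal

from .signal import ECGSignal

#: Conventional software band-pass for wearable ECG at 360 Hz.
DEFAULT_F_LO = 0.5
DEFAULT_F_HI = 100.0
DEFAULT_FS = 360.0
DEFAULT_ORDER = 2


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass corner frequencies and order.

    ``f_lo`` removes sub-cardiac drift (respiration, electrode motion);
    ``f_hi`` suppresses high-frequency noise while keeping QRS energy.
    """

    f_lo: float = DEFAULT_F_LO
    f_hi: float = DEFAULT_F_HI
    order: int = DEFAULT_ORDER
    fs: float = DEFAULT_FS

    def __post_init__(self) -> None:
        if not 0 < self.f_lo < self.f_hi:
            raise ValueError(f"need 0 < f_lo < f_hi, got ({self.f_lo}, {self.f_hi})")
        if self.f_hi >= self.fs / 2:
            raise ValueError(
                f"high cut {self.f_hi} Hz violates Nyquist for fs={self.fs} Hz"
            )
        if self.order < 1:
            raise ValueError("filter order must be >= 1")


@dataclass(frozen=True)
class MedianSpec:
    """Median filter window in samples. Must be odd so the window has a center."""

    window: int = 3

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError(f"median window must be odd and >= 1, got {self.window}")


def response_magnitude(f, fc: float, n: int = 1):
    """Ideal band-edge magnitude response ``1 / (1 + (f/fc)^(2n))``.

    Equals 1 at ``f = 0``, exactly 0.5 at ``f = fc`` for every order ``n``,
    and decreases monotonically with ``f``; larger ``n`` sharpens the
    transition around the cut-off. Accepts scalar or array ``f``.
    """
    if fc <= 0:
        raise ValueError(f"cut-off frequency must be positive, got {fc}")
    if n < 1:
        raise ValueError(f"order must be >= 1, got {n}")
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative")
    out = 1.0 / (1.0 + (f / fc) ** (2 * n))
    return float(out) if out.ndim == 0 else out


def bandpass_filter(signal: ECGSignal, spec: FilterSpec | None = None) -> ECGSignal:
    """Zero-phase Butterworth band-pass.

    Applied forward and backward (``filtfilt``) so fiducial points are not
    systematically delayed. Output length equals input length.
    """
    if spec is None:
        spec = FilterSpec(fs=signal.fs)
    if spec.fs != signal.fs:
        raise ValueError(f"spec fs {spec.fs} != signal fs {signal.fs}")
    min_len = 3 * (2 * spec.order + 1)
    if len(signal) <= min_len:
        raise ValueError(f"signal too short ({len(signal)}) for order-{spec.order} band-pass")
    sos = scipy.signal.butter(
        spec.order, [spec.f_lo, spec.f_hi], btype="bandpass", fs=spec.fs, output="sos"
    )
    return signal.replace(scipy.signal.sosfiltfilt(sos, signal.samples))


def median_filter(signal: ECGSignal, spec: MedianSpec | None = None) -> ECGSignal:
    """Running median with edge replication at the boundaries.

    Removes isolated spike samples while leaving monotone ramps (and hence
    wave flanks wider than the window) untouched. ``window=1`` is the identity.
    """
    if spec is None:
        spec = MedianSpec()
    if spec.window > len(signal):
        raise ValueError(f"median window {spec.window} exceeds signal length {len(signal)}")
    if spec.window == 1:
        return signal.replace(signal.samples.copy())
    out = scipy.ndimage.median_filter(signal.samples, size=spec.window, mode="nearest")
    return signal.replace(out)


def notch_filter(signal: ECGSignal, mains: float = 50.0, q: float = 30.0) -> ECGSignal:
    """Zero-phase IIR notch suppressing powerline interference at ``mains`` Hz.

    ``q`` is the notch quality factor (center frequency over −3 dB bandwidth);
    the default gives a ~1.7 Hz-wide notch at 50 Hz, narrow enough to leave
    QRS spectral content intact.
    """
    if mains <= 0 or mains >= signal.fs / 2:
        raise ValueError(f"mains frequency {mains} Hz must lie in (0, fs/2) for fs={signal.fs}")
    b, a = scipy.signal.iirnotch(mains, q, fs=signal.fs)
    return signal.replace(scipy.signal.filtfilt(b, a, signal.samples))


def suppress_noise(
    signal: ECGSignal,
    filter_spec: FilterSpec | None = None,
    median_spec: MedianSpec | None = None,
    mains: float | None = 50.0,
) -> ECGSignal:
    """Default chain: median -> band-pass -> notch.

    The median stage runs first so spike samples cannot ring through the IIR
    stages; pass ``mains=None`` to skip the notch.
    """
    out = median_filter(signal, median_spec)
    out = bandpass_filter(out, filter_spec)
    if mains is not None:
        out = notch_filter(out, mains)
    return out
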
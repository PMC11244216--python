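"""PQRST fiducial-point delineation.

R peaks are found first (local maxima over an adaptive threshold with a
refractory period); the remaining points are located by windowed extremum
searches around each R:

* Q: minimum over ``[R - q_win, R)`` — the trough just before the R upstroke,
* S: minimum over ``(R, R + s_win]`` — the trough just after,
* T: maximum over ``(S, S + t_win]`` — ventricular repolarization,
* P: maximum over ``[Q - p_win_far, Q - p_win_near]`` — atrial depolarization.

Window durations are the conventional values at 360 Hz (0.04 s -> 14.4
samples for Q, 0.08 s -> 28.8 for S, 0.2 s -> 72 for T); fractional windows
are floored. The default durations describe beats near 60 bpm;
:meth:`FiducialWindows.for_heart_rate` rescales them with sqrt(RR)
(Bazett-style) so tachycardic beats keep their waves inside the search
windows.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from math import floor, sqrt

import numpy as np
import pandas as pd

from .signal import ECGSignal

logger = logging.getLogger(__name__)

#: Column order of the fiducial-table CSV schema.
FIDUCIAL_COLUMNS = ["Q_Points", "R_Peaks", "S_Points", "T_Points", "P_Points"]

#: Same columns in temporal order within a beat.
TEMPORAL_ORDER = ["P_Points", "Q_Points", "R_Peaks", "S_Points", "T_Points"]


def window_samples(duration: float, fs: float) -> float:
    """Window length in samples, pre-rounding: ``duration * fs``.

    Returned as a float (0.04 s at 360 Hz is 14.4 samples); integer windows
    floor this value.
    """
    if duration <= 0 or fs <= 0:
        raise ValueError("duration and fs must be positive")
    return duration * fs


@dataclass(frozen=True)
class FiducialWindows:
    """Search-window durations (seconds) around each beat's R peak."""

    q_win: float = 0.04
    s_win: float = 0.08
    t_win: float = 0.2
    p_win_near: float = 0.12
    p_win_far: float = 0.20
    fs: float = 360.0

    def __post_init__(self) -> None:
        for name in ("q_win", "s_win", "t_win", "p_win_near", "p_win_far"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.p_win_far > self.p_win_near:
            raise ValueError("p_win_far must exceed p_win_near")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    def scaled(self, factor: float) -> "FiducialWindows":
        """All durations multiplied by ``factor`` (fs unchanged)."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return replace(
            self,
            q_win=self.q_win * factor,
            s_win=self.s_win * factor,
            t_win=self.t_win * factor,
            p_win_near=self.p_win_near * factor,
            p_win_far=self.p_win_far * factor,
        )

    @classmethod
    def for_heart_rate(cls, heart_rate: float, fs: float = 360.0) -> "FiducialWindows":
        """Windows rescaled by sqrt(RR) relative to the 60 bpm defaults.

        Wave-to-R latencies shorten roughly with the square root of the beat
        period as rate increases, so the search windows shrink the same way.
        """
        if not 0 < heart_rate:
            raise ValueError("heart_rate must be positive")
        return cls(fs=fs).scaled(sqrt(60.0 / heart_rate))

    # integer window lengths (floored), in samples
    @property
    def q_n(self) -> int:
        return floor(window_samples(self.q_win, self.fs))

    @property
    def s_n(self) -> int:
        return floor(window_samples(self.s_win, self.fs))

    @property
    def t_n(self) -> int:
        return floor(window_samples(self.t_win, self.fs))

    @property
    def p_near_n(self) -> int:
        return floor(window_samples(self.p_win_near, self.fs))

    @property
    def p_far_n(self) -> int:
        return floor(window_samples(self.p_win_far, self.fs))


def _local_maxima(x: np.ndarray) -> np.ndarray:
    """Indices of strict-left / weak-right local maxima.

    A plateau of equal maxima yields its first index, so ties break to the
    earlier sample.
    """
    if len(x) < 2:
        return np.arange(len(x))
    left = np.concatenate(([-np.inf], x[:-1]))
    right = np.concatenate((x[1:], [-np.inf]))
    return np.nonzero((x > left) & (x >= right))[0]


def detect_r_peaks(
    signal: ECGSignal,
    min_rr: float = 0.2,
    threshold_factor: float = 0.5,
    quantile: float = 1.0,
    window_s: float = 2.0,
) -> np.ndarray:
    """R-peak indices on a filtered, polarity-corrected signal.

    Candidates are local maxima above ``threshold_factor`` times a rolling
    amplitude statistic (the rolling maximum by default, i.e. ``quantile=1``),
    computed over ``window_s``-second windows so the threshold tracks slow
    gain changes. Candidates closer than ``min_rr`` seconds are resolved
    greedily by amplitude, earlier index winning ties. The detector is
    equivariant to positive amplitude scaling.
    """
    x = signal.samples
    n_refractory = int(round(min_rr * signal.fs))
    if len(x) < max(2, n_refractory):
        return np.array([], dtype=int)
    win = max(3, int(round(window_s * signal.fs)))
    roll = (
        pd.Series(x).rolling(win, center=True, min_periods=1).quantile(quantile).to_numpy()
    )
    threshold = threshold_factor * roll
    cand = _local_maxima(x)
    cand = cand[(x[cand] > threshold[cand]) & (x[cand] > 0)]
    if len(cand) == 0:
        return np.array([], dtype=int)
    # greedy refractory resolution: strongest first, earlier on amplitude ties
    order = np.lexsort((cand, -x[cand]))
    kept: list[int] = []
    for i in cand[order]:
        if all(abs(i - j) >= n_refractory for j in kept):
            kept.append(int(i))
    return np.array(sorted(kept), dtype=int)


def _argmin_in(x: np.ndarray, lo: int, hi: int) -> int:
    """First minimum index in ``x[lo:hi]`` (absolute index)."""
    return lo + int(np.argmin(x[lo:hi]))


def _argmax_in(x: np.ndarray, lo: int, hi: int) -> int:
    return lo + int(np.argmax(x[lo:hi]))


def detect_fiducials(
    signal: ECGSignal,
    r_peaks: np.ndarray,
    windows: FiducialWindows | None = None,
) -> pd.DataFrame:
    """Locate Q, S, T and P around each R peak; emit the fiducial table.

    Beats whose search windows run off the signal, or whose located points
    violate the temporal order P < Q < R < S < T, are dropped with a warning.
    Returns a DataFrame with columns ``Q_Points, R_Peaks, S_Points, T_Points,
    P_Points`` (integer sample indices, one row per retained beat).
    """
    if windows is None:
        windows = FiducialWindows(fs=signal.fs)
    x = signal.samples
    n = len(x)
    rows = []
    dropped = 0
    for r in np.asarray(r_peaks, dtype=int):
        q_lo = r - windows.q_n
        s_hi = r + windows.s_n
        if q_lo < 0 or s_hi >= n or r == 0:
            dropped += 1
            continue
        q = _argmin_in(x, q_lo, r)          # [R - q_win, R)
        s = _argmin_in(x, r + 1, s_hi + 1)  # (R, R + s_win]
        t_hi = s + windows.t_n
        p_lo = q - windows.p_far_n
        p_hi = q - windows.p_near_n
        if t_hi >= n or p_lo < 0 or p_hi < p_lo:
            dropped += 1
            continue
        t = _argmax_in(x, s + 1, t_hi + 1)  # (S, S + t_win]
        p = _argmax_in(x, p_lo, p_hi + 1)   # [Q - p_far, Q - p_near]
        if not (p < q < r < s < t):
            dropped += 1
            continue
        rows.append((q, r, s, t, p))
    if dropped:
        msg = f"dropped {dropped} beat(s) with out-of-bounds windows or disordered points"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    return pd.DataFrame(rows, columns=FIDUCIAL_COLUMNS, dtype=int)


def delineate(
    signal: ECGSignal,
    windows: FiducialWindows | None = None,
    min_rr: float = 0.2,
    threshold_factor: float = 0.5,
) -> pd.DataFrame:
    """Convenience wrapper: R detection followed by windowed delineation."""
    r = detect_r_peaks(signal, min_rr=min_rr, threshold_factor=threshold_factor)
    return detect_fiducials(signal, r, windows)


def validate_fiducial_table(table: pd.DataFrame) -> list[str]:
    """Return a list of invariant violations ('' empty when the table is valid).

    Checks the schema, per-row temporal order P < Q < R < S < T,
    non-negative indices, and strictly increasing R across rows.
    """
    problems: list[str] = []
    missing = [c for c in FIDUCIAL_COLUMNS if c not in table.columns]
    if missing:
        return [f"missing columns: {', '.join(missing)}"]
    arr = table[TEMPORAL_ORDER].to_numpy()
    if len(arr) and arr.min() < 0:
        problems.append("negative sample indices present")
    bad = np.nonzero(~np.all(np.diff(arr, axis=1) > 0, axis=1))[0]
    for i in bad:
        problems.append(f"row {table.index[i]}: temporal order P<Q<R<S<T violated")
    r = table["R_Peaks"].to_numpy()
    if len(r) > 1 and not np.all(np.diff(r) > 0):
        problems.append("R_Peaks not strictly increasing across rows")
    return problems
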
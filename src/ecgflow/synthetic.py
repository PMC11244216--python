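"""Seeded generators for ECG traces and patient cohorts with known truth.

The beat model is a sum of Gaussian bumps, one per wave, in conventional
lead-II polarity: P, R, T positive; Q, S negative; R the dominant per-beat
extremum. Wave latencies and widths are specified at a 1 s beat period and
rescaled by sqrt(RR) at other heart rates, so the QT interval shortens with
rate the way real beats do. On top of the clean trace the generator can add
baseline wander (slow sinusoid), mains interference, isolated impulse
spikes, and white noise — the artifact classes the preprocessing chain
targets — and optionally invert the whole trace.

The patient-cohort generator emulates a 132-participant cardiology-clinic
table: binary risk factors drawn at specified rates, age uniform on a range,
blood pressure and cholesterol truncated-normal, and a binary condition
outcome from a logistic link on the (standardized) features so downstream
classifiers have signal to find.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import sqrt

import numpy as np
import pandas as pd
import scipy.stats

from .fiducials import FIDUCIAL_COLUMNS, TEMPORAL_ORDER
from .signal import ECGSignal

WAVES = ("P", "Q", "R", "S", "T")
_WAVE_TO_COLUMN = {
    "P": "P_Points",
    "Q": "Q_Points",
    "R": "R_Peaks",
    "S": "S_Points",
    "T": "T_Points",
}

#: Table-5 patient-table header, in schema order.
PATIENT_COLUMNS = [
    "Age",
    "Sex",
    "Chest Pain",
    "Blood Pressure",
    "Cholesterol",
    "Alcohol",
    "Diabetes",
    "ECG Change",
    "Smoking",
    "Condition",
]


@dataclass(frozen=True)
class BeatTemplate:
    """Per-wave Gaussian parameters at a reference beat period of 1 s.

    ``offsets`` are wave centers relative to R (seconds, P and Q negative);
    ``widths`` are Gaussian standard deviations (seconds); ``amplitudes``
    signed, in arbitrary units. Q and S must be negative, P/R/T positive,
    and offsets must respect the temporal order P < Q < R=0 < S < T.
    """

    amplitudes: dict = field(
        default_factory=lambda: {"P": 0.15, "Q": -0.12, "R": 1.0, "S": -0.25, "T": 0.35}
    )
    offsets: dict = field(
        default_factory=lambda: {"P": -0.18, "Q": -0.035, "R": 0.0, "S": 0.04, "T": 0.22}
    )
    widths: dict = field(
        default_factory=lambda: {"P": 0.025, "Q": 0.008, "R": 0.01, "S": 0.009, "T": 0.05}
    )

    def __post_init__(self) -> None:
        for w in WAVES:
            for d in (self.amplitudes, self.offsets, self.widths):
                if w not in d:
                    raise ValueError(f"template missing wave {w}")
            if self.widths[w] <= 0:
                raise ValueError(f"width of {w} must be positive")
        o = self.offsets
        if not (o["P"] < o["Q"] < o["R"] == 0.0 < o["S"] < o["T"]):
            raise ValueError("offsets must satisfy P < Q < R=0 < S < T")
        for w in ("P", "R", "T"):
            if self.amplitudes[w] <= 0:
                raise ValueError(f"{w} amplitude must be positive")
        for w in ("Q", "S"):
            if self.amplitudes[w] >= 0:
                raise ValueError(f"{w} amplitude must be negative")

    def scaled(self, rr: float) -> "BeatTemplate":
        """Template at beat period ``rr`` seconds: latencies and widths times sqrt(RR)."""
        b = sqrt(rr)
        return replace(
            self,
            offsets={w: v * b if w != "R" else 0.0 for w, v in self.offsets.items()},
            widths={w: v * b for w, v in self.widths.items()},
        )


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings: geometry, noise amplitudes, inversion, seed.

    Noise defaults are moderate relative to the unit R amplitude — enough to
    exercise every preprocessing stage without burying the waves. Set the
    four noise amplitudes (``white_sd``, ``baseline_amp``, ``mains_amp``,
    ``impulse_rate``) to 0 for a clean trace.
    """

    fs: float = 360.0
    duration: float = 10.0
    heart_rate: float = 60.0
    white_sd: float = 0.02
    baseline_amp: float = 0.15
    baseline_freq: float = 0.25
    mains_amp: float = 0.10
    mains_freq: float = 50.0
    impulse_rate: float = 0.2   # expected spikes per second
    impulse_amp: float = 1.0
    rr_jitter: float = 0.02     # uniform fractional jitter on each RR interval
    inverted: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")
        if not 20 <= self.heart_rate <= 250:
            raise ValueError(f"heart_rate {self.heart_rate} outside [20, 250] bpm")
        for name in ("white_sd", "baseline_amp", "mains_amp", "impulse_rate", "impulse_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.mains_freq not in (50.0, 60.0, 50, 60):
            raise ValueError("mains_freq must be 50 or 60 Hz")
        if not 0 <= self.rr_jitter < 0.5:
            raise ValueError("rr_jitter must be in [0, 0.5)")

    def clean(self) -> "SynthConfig":
        """Copy with all noise sources switched off."""
        return replace(self, white_sd=0.0, baseline_amp=0.0, mains_amp=0.0, impulse_rate=0.0)


@dataclass(frozen=True)
class GroundTruth:
    """True per-beat fiducial sample indices plus the inversion flag.

    ``table`` uses the fiducial-table schema (Q_Points, R_Peaks, S_Points,
    T_Points, P_Points); each row satisfies P < Q < R < S < T.
    """

    table: pd.DataFrame
    inverted: bool

    def __post_init__(self) -> None:
        arr = self.table[TEMPORAL_ORDER].to_numpy()
        if len(arr) and not np.all(np.diff(arr, axis=1) > 0):
            raise ValueError("ground-truth rows must satisfy P<Q<R<S<T")

    def __len__(self) -> int:
        return len(self.table)

    def column(self, wave: str) -> np.ndarray:
        return self.table[_WAVE_TO_COLUMN[wave]].to_numpy()


def _render_clean(
    n: int, fs: float, r_times: np.ndarray, tpl: BeatTemplate
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render Gaussian-bump beats and locate each wave's true extremum."""
    x = np.zeros(n)
    t = np.arange(n) / fs
    for r_time in r_times:
        for w in WAVES:
            c = r_time + tpl.offsets[w]
            sd = tpl.widths[w]
            lo = max(0, int((c - 5 * sd) * fs))
            hi = min(n, int((c + 5 * sd) * fs) + 1)
            if lo < hi:
                x[lo:hi] += tpl.amplitudes[w] * np.exp(
                    -0.5 * ((t[lo:hi] - c) / sd) ** 2
                )
    # truth = local extremum of the clean signal near each wave center,
    # searched within 2.5 sd but never past the midpoint to a neighbor wave
    rows = []
    order = ["P", "Q", "R", "S", "T"]
    for r_time in r_times:
        centers = {w: (r_time + tpl.offsets[w]) * fs for w in WAVES}
        idx = {}
        ok = True
        for w in WAVES:
            k = order.index(w)
            radius = 2.5 * tpl.widths[w] * fs
            if k > 0:
                radius = min(radius, (centers[w] - centers[order[k - 1]]) / 2)
            if k < len(order) - 1:
                radius = min(radius, (centers[order[k + 1]] - centers[w]) / 2)
            radius = max(radius, 1.0)
            lo = int(np.ceil(centers[w] - radius))
            hi = int(np.floor(centers[w] + radius)) + 1
            if lo < 0 or hi > n:
                ok = False
                break
            seg = x[lo:hi]
            pick = np.argmax(seg) if tpl.amplitudes[w] > 0 else np.argmin(seg)
            idx[w] = lo + int(pick)
        if ok and idx["P"] < idx["Q"] < idx["R"] < idx["S"] < idx["T"]:
            rows.append([idx[w] for w in ("Q", "R", "S", "T", "P")])
    truth = pd.DataFrame(rows, columns=FIDUCIAL_COLUMNS, dtype=int)
    return x, truth


def generate_ecg(
    config: SynthConfig, template: BeatTemplate | None = None
) -> tuple[ECGSignal, GroundTruth]:
    """Synthesize a multi-beat ECG trace with per-beat ground-truth fiducials.

    The trace is a pure function of ``config`` (including its seed).
    Inversion is applied as a final global sign flip, so the same config with
    ``inverted`` toggled yields the exact sample-wise negation. Ground-truth
    rows cover only beats fully contained in the trace.
    """
    if template is None:
        template = BeatTemplate()
    n = int(round(config.fs * config.duration))
    rng = np.random.default_rng(config.seed)
    rr = 60.0 / config.heart_rate
    tpl = template.scaled(rr)

    # beat grid with uniform fractional jitter on each interval
    lead_in = -tpl.offsets["P"] + 4 * tpl.widths["P"]
    tail = tpl.offsets["T"] + 4 * tpl.widths["T"]
    r_times = []
    t_r = lead_in + 0.1 * rr
    while t_r + tail < config.duration:
        r_times.append(t_r)
        jitter = rng.uniform(-config.rr_jitter, config.rr_jitter) if config.rr_jitter else 0.0
        t_r = t_r + rr * (1.0 + jitter)
    r_times = np.asarray(r_times)

    x, truth = _render_clean(n, config.fs, r_times, tpl)

    # noise terms are always drawn in the same order so that the seed alone
    # fixes them regardless of which amplitudes are zero
    t = np.arange(n) / config.fs
    phase_bw = rng.uniform(0, 2 * np.pi)
    phase_mains = rng.uniform(0, 2 * np.pi)
    n_spikes = rng.poisson(config.impulse_rate * config.duration)
    spike_pos = rng.integers(0, n, size=n_spikes)
    spike_sign = rng.choice([-1.0, 1.0], size=n_spikes)
    white = rng.normal(0.0, 1.0, size=n)

    if config.baseline_amp:
        x = x + config.baseline_amp * np.sin(2 * np.pi * config.baseline_freq * t + phase_bw)
    if config.mains_amp:
        x = x + config.mains_amp * np.sin(2 * np.pi * config.mains_freq * t + phase_mains)
    if config.impulse_rate and config.impulse_amp:
        np.add.at(x, spike_pos, spike_sign * config.impulse_amp)
    if config.white_sd:
        x = x + config.white_sd * white

    if config.inverted:
        x = -x
    return ECGSignal(x, config.fs), GroundTruth(truth, config.inverted)


@dataclass(frozen=True)
class CohortMarginals:
    """Target marginal structure of the synthetic patient cohort.

    Defaults reproduce the study cohort: 98/132 male, ages 28–68, mean blood
    pressure 129.93 mmHg on [94, 200], cholesterol on [126, 341], and binary
    risk-factor rates of 43.18% alcohol, 31.06% diabetes, 55.30% smoking,
    37.12% ECG change. The condition outcome follows a logistic link on the
    standardized features with the coefficients below; ``margin`` switches to
    a deterministic wide-margin rule (rows with logit magnitude below the
    margin are resampled), yielding a linearly separable cohort for
    classifier stress tests.
    """

    sex_male: float = 98 / 132
    chest_pain: float = 0.45
    alcohol: float = 0.4318
    diabetes: float = 0.3106
    smoking: float = 0.5530
    ecg_change: float = 0.3712
    age_range: tuple = (28, 68)
    bp_mean: float = 129.93
    bp_sd: float = 12.0
    bp_range: tuple = (94.0, 200.0)
    chol_mean: float = 225.0
    chol_sd: float = 40.0
    chol_range: tuple = (126.0, 341.0)
    coefficients: dict = field(
        default_factory=lambda: {
            "Age": 0.8,
            "Sex": 0.2,
            "Chest Pain": 0.9,
            "Blood Pressure": 0.7,
            "Cholesterol": 0.6,
            "Alcohol": 0.3,
            "Diabetes": 0.8,
            "ECG Change": 1.0,
            "Smoking": 0.6,
        }
    )
    intercept: float = 0.2
    margin: float | None = None

    def __post_init__(self) -> None:
        for name in ("sex_male", "chest_pain", "alcohol", "diabetes", "smoking", "ecg_change"):
            r = getattr(self, name)
            if not 0 <= r <= 1:
                raise ValueError(f"rate {name}={r} outside [0, 1]")
        for name in ("age_range", "bp_range", "chol_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be an increasing (lo, hi) pair")
        if self.bp_sd <= 0 or self.chol_sd <= 0:
            raise ValueError("bp_sd and chol_sd must be positive")
        if self.margin is not None and self.margin < 0:
            raise ValueError("margin must be non-negative")

    def separable(self, margin: float = 2.5) -> "CohortMarginals":
        """Copy with the deterministic wide-margin outcome rule enabled."""
        return replace(self, margin=margin)


def _trunc_normal(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return scipy.stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _cohort_batch(rng, n: int, m: CohortMarginals) -> pd.DataFrame:
    age = rng.integers(m.age_range[0], m.age_range[1] + 1, size=n)
    df = pd.DataFrame(
        {
            "Age": age,
            "Sex": (rng.random(n) < m.sex_male).astype(int),
            "Chest Pain": (rng.random(n) < m.chest_pain).astype(int),
            "Blood Pressure": np.round(_trunc_normal(rng, m.bp_mean, m.bp_sd, *m.bp_range, n), 0),
            "Cholesterol": np.round(_trunc_normal(rng, m.chol_mean, m.chol_sd, *m.chol_range, n), 0),
            "Alcohol": (rng.random(n) < m.alcohol).astype(int),
            "Diabetes": (rng.random(n) < m.diabetes).astype(int),
            "ECG Change": (rng.random(n) < m.ecg_change).astype(int),
            "Smoking": (rng.random(n) < m.smoking).astype(int),
        }
    )
    return df


def _cohort_logit(df: pd.DataFrame, m: CohortMarginals) -> np.ndarray:
    """Linear risk score: standardized continuous terms, rate-centered binaries."""
    lo, hi = m.age_range
    age_mean, age_sd = (lo + hi) / 2, (hi - lo) / sqrt(12)
    z = np.full(len(df), m.intercept)
    scale = {
        "Age": (age_mean, age_sd),
        "Blood Pressure": (m.bp_mean, m.bp_sd),
        "Cholesterol": (m.chol_mean, m.chol_sd),
    }
    center = {
        "Sex": m.sex_male,
        "Chest Pain": m.chest_pain,
        "Alcohol": m.alcohol,
        "Diabetes": m.diabetes,
        "ECG Change": m.ecg_change,
        "Smoking": m.smoking,
    }
    for col, beta in m.coefficients.items():
        v = df[col].to_numpy(dtype=float)
        if col in scale:
            mu, sd = scale[col]
            v = (v - mu) / sd
        else:
            v = v - center[col]
        z = z + beta * v
    return z


def generate_patient_table(
    n: int, marginals: CohortMarginals | None = None, seed: int = 0
) -> pd.DataFrame:
    """Synthetic patient cohort with the Table-5 schema and given marginals.

    Deterministic given ``(n, marginals, seed)``. With the default logistic
    outcome the condition carries learnable but noisy signal; with
    ``marginals.margin`` set, outcomes are a deterministic threshold on the
    risk score and rows inside the margin band are resampled, giving a
    wide-margin separable cohort.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    m = marginals if marginals is not None else CohortMarginals()
    rng = np.random.default_rng(seed)

    if m.margin is None:
        df = _cohort_batch(rng, n, m)
        z = _cohort_logit(df, m)
        df["Condition"] = (rng.random(n) < 1.0 / (1.0 + np.exp(-z))).astype(int)
        return df[PATIENT_COLUMNS]

    parts: list[pd.DataFrame] = []
    got = 0
    while got < n:
        batch = _cohort_batch(rng, max(2 * (n - got), 32), m)
        z = _cohort_logit(batch, m)
        keep = np.abs(z) >= m.margin
        batch = batch.loc[keep].copy()
        batch["Condition"] = (z[keep] > 0).astype(int)
        parts.append(batch)
        got += len(batch)
    df = pd.concat(parts, ignore_index=True).iloc[:n].reset_index(drop=True)
    return df[PATIENT_COLUMNS]


def inject_fiducial_outliers(
    table: pd.DataFrame, k: int, magnitude: float, seed: int = 0
) -> tuple[pd.DataFrame, np.ndarray]:
    """Shift ``k`` randomly chosen rows of a fiducial table by ``magnitude`` samples.

    All five fiducial columns of a chosen row are offset together, preserving
    the within-beat order while displacing the beat far from the row-wise
    trend — a known-truth anomaly for testing beat-level outlier detectors.
    Unchosen rows are returned bit-identical. Returns the perturbed table and
    the sorted array of perturbed row positions.
    """
    n = len(table)
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, {n}]")
    if k and magnitude <= 0:
        raise ValueError("magnitude must be positive")
    out = table.copy()
    if k == 0:
        return out, np.array([], dtype=int)
    rng = np.random.default_rng(seed)
    rows = np.sort(rng.choice(n, size=k, replace=False))
    shift = int(round(magnitude))
    out.iloc[rows, [out.columns.get_loc(c) for c in FIDUCIAL_COLUMNS]] += shift
    return out, rows
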
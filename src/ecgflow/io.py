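"""CSV readers and writers for the pipeline's tabular schemas.

Three schemas, all UTF-8 comma-separated with a mandatory header row:

* signal — ``sample_index,amplitude`` (a one-column ``amplitude`` dialect is
  also accepted; the index column is never used as data),
* fiducial table — ``Index,Q_Points,R_Peaks,S_Points,T_Points,P_Points``
  (index column optional; an ``Anomaly`` column of ±1 labels may follow),
* patient table — ``Age,Sex,Chest Pain,Blood Pressure,Cholesterol,Alcohol,
  Diabetes,ECG Change,Smoking,Condition``.

Readers validate hard (non-numeric cells and NaNs are errors with row
numbers; missing schema columns are schema errors) and tolerate soft
deviations (unknown extra columns are ignored with a warning; fiducial rows
violating the temporal-order invariant are rejected with a report).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .anomaly import ANOMALY_COLUMN
from .fiducials import FIDUCIAL_COLUMNS, TEMPORAL_ORDER
from .signal import ECGSignal
from .synthetic import PATIENT_COLUMNS


class SchemaError(ValueError):
    """A file does not match its expected CSV schema."""


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file") from None
    if len(df) == 0:
        raise SchemaError(f"{path}: no data rows")
    return df


def read_signal(path, fs: float = 360.0) -> ECGSignal:
    """Load an ECG trace from a 1- or 2-column CSV.

    A 2-column file must name an ``amplitude`` column (the other column is
    treated as a sample index and ignored); a 1-column file is taken as
    amplitudes regardless of its header. Non-numeric or missing cells raise
    with the offending row number.
    """
    df = _read_csv(path)
    if "amplitude" in df.columns:
        col = df["amplitude"]
    elif len(df.columns) == 1:
        col = df.iloc[:, 0]
    else:
        raise SchemaError(
            f"{path}: expected an 'amplitude' column, found {list(df.columns)}"
        )
    values = pd.to_numeric(col, errors="coerce")
    bad = np.nonzero(~np.isfinite(values.to_numpy(dtype=float)))[0]
    if len(bad):
        raise SchemaError(f"{path}: non-numeric or missing amplitude at data row {bad[0]}")
    return ECGSignal(values.to_numpy(dtype=float), fs)


def write_signal(path, signal: ECGSignal) -> None:
    """Write ``sample_index,amplitude`` CSV."""
    df = pd.DataFrame(
        {"sample_index": np.arange(len(signal)), "amplitude": signal.samples}
    )
    # %.17g keeps the write -> read round trip bit-exact for doubles
    df.to_csv(path, index=False, float_format="%.17g")


def read_fiducial_table(path, validate: bool = True) -> pd.DataFrame:
    """Load a fiducial table, enforcing the five-column schema.

    Unknown columns (other than ``Index`` and ``Anomaly``) are dropped with
    a warning. With ``validate=True`` rows violating P < Q < R < S < T or
    carrying negative indices are rejected, with a per-row report in the
    warning message.
    """
    df = _read_csv(path)
    missing = [c for c in FIDUCIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s): {', '.join(missing)}")
    keep = FIDUCIAL_COLUMNS + ([ANOMALY_COLUMN] if ANOMALY_COLUMN in df.columns else [])
    extra = [c for c in df.columns if c not in keep + ["Index"]]
    if extra:
        warnings.warn(f"{path}: ignoring unknown column(s): {', '.join(extra)}", stacklevel=2)
    df = df[keep]
    for col in keep:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(~np.isfinite(values.to_numpy(dtype=float)))[0]
        if len(bad):
            raise SchemaError(f"{path}: non-numeric cell in {col!r} at data row {bad[0]}")
    df = df.astype(int)
    if validate:
        arr = df[TEMPORAL_ORDER].to_numpy()
        ok = np.all(np.diff(arr, axis=1) > 0, axis=1) & (arr.min(axis=1) >= 0)
        if not ok.all():
            rejected = np.nonzero(~ok)[0]
            warnings.warn(
                f"{path}: rejected {len(rejected)} row(s) violating fiducial "
                f"invariants: rows {rejected.tolist()}",
                stacklevel=2,
            )
            df = df.loc[ok].reset_index(drop=True)
    return df


def write_fiducial_table(path, table: pd.DataFrame) -> None:
    """Write a fiducial table (with its anomaly column if present)."""
    cols = FIDUCIAL_COLUMNS + ([ANOMALY_COLUMN] if ANOMALY_COLUMN in table.columns else [])
    out = table[cols].copy()
    out.insert(0, "Index", np.arange(len(out)))
    out.to_csv(path, index=False)


def read_patient_table(path) -> pd.DataFrame:
    """Load a patient table with the ten-column schema; validates hard."""
    df = _read_csv(path)
    missing = [c for c in PATIENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s): {', '.join(missing)}")
    extra = [c for c in df.columns if c not in PATIENT_COLUMNS]
    if extra:
        warnings.warn(f"{path}: ignoring unknown column(s): {', '.join(extra)}", stacklevel=2)
    df = df[PATIENT_COLUMNS]
    for col in PATIENT_COLUMNS:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(~np.isfinite(values.to_numpy(dtype=float)))[0]
        if len(bad):
            raise SchemaError(f"{path}: non-numeric cell in {col!r} at data row {bad[0]}")
    from .risk import validate_patient_table

    out = df.apply(pd.to_numeric)
    validate_patient_table(out)
    return out


def write_patient_table(path, table: pd.DataFrame) -> None:
    table[PATIENT_COLUMNS].to_csv(path, index=False)
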
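"""Isolation Forest labelling of fiducial-table rows.

Each row of a fiducial table describes one beat by its five wave indices.
An Isolation Forest (100 trees, automatic contamination threshold, fixed
random state) scores how easily each beat is isolated by random
axis-parallel splits; short isolation paths mark anomalous beats. Labels
follow the +1 normal / -1 anomalous convention and are appended to the
table, which is otherwise preserved verbatim.

Two feature modes are offered:

* ``"raw"`` — the five index columns as printed in the table. This is the
  simplest choice but the indices grow with recording time, so anomalies
  must displace a beat relative to that trend to be visible.
* ``"intervals"`` — derived per-beat durations (RR to the previous beat,
  PR, QRS, QT, ST in samples), which are stationary in recording time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import IsolationForest

from .fiducials import FIDUCIAL_COLUMNS

ANOMALY_COLUMN = "Anomaly"


@dataclass(frozen=True)
class AnomalyModelSpec:
    """Isolation Forest configuration: 100 trees, auto contamination, seed 42."""

    n_estimators: int = 100
    contamination: str | float = "auto"
    random_state: int = 42
    max_samples: str | int | float = "auto"
    features: str = "raw"  # "raw" | "intervals"

    def __post_init__(self) -> None:
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        if self.features not in ("raw", "intervals"):
            raise ValueError(f"unknown feature mode {self.features!r}")


def interval_features(table: pd.DataFrame) -> pd.DataFrame:
    """Per-beat durations in samples: RR (previous beat), PR, QRS, QT, ST.

    The first row's RR is backfilled with the second row's so every row has
    a complete feature vector.
    """
    f = pd.DataFrame(index=table.index)
    rr = table["R_Peaks"].diff()
    if len(rr) > 1:
        rr.iloc[0] = rr.iloc[1]
    f["RR"] = rr
    f["PR"] = table["R_Peaks"] - table["P_Points"]
    f["QRS"] = table["S_Points"] - table["Q_Points"]
    f["QT"] = table["T_Points"] - table["Q_Points"]
    f["ST"] = table["T_Points"] - table["S_Points"]
    return f


def _feature_matrix(table: pd.DataFrame, spec: AnomalyModelSpec) -> np.ndarray:
    if spec.features == "intervals":
        return interval_features(table).to_numpy(dtype=float)
    return table[FIDUCIAL_COLUMNS].to_numpy(dtype=float)


def fit_predict_anomalies(table: pd.DataFrame, spec: AnomalyModelSpec | None = None) -> pd.DataFrame:
    """Label each beat +1 (normal) or -1 (anomalous) and append the column.

    Deterministic for a fixed spec and table (the forest's random state is
    part of the spec). Input rows and columns are preserved verbatim; only
    the ``Anomaly`` column is added.
    """
    if spec is None:
        spec = AnomalyModelSpec()
    missing = [c for c in FIDUCIAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"fiducial table missing columns: {', '.join(missing)}")
    if len(table) < 2:
        raise ValueError("need at least 2 rows to fit the anomaly model")
    x = _feature_matrix(table, spec)
    if not np.all(np.isfinite(x)):
        raise ValueError("fiducial table contains missing or non-numeric values")
    forest = IsolationForest(
        n_estimators=spec.n_estimators,
        contamination=spec.contamination,
        max_samples=spec.max_samples,
        random_state=spec.random_state,
    )
    labels = forest.fit_predict(x)
    out = table.copy()
    out[ANOMALY_COLUMN] = labels.astype(int)
    return out


def summarize_by_label(labeled: pd.DataFrame) -> pd.DataFrame:
    """Per-column means within each label group (anomalous vs normal).

    Returns a frame indexed by the fiducial columns (plus the label column
    itself) with columns ``Anomalous Means`` and ``Normal Means``; a group
    with no rows yields NaN, never zero.
    """
    if len(labeled) == 0:
        raise ValueError("labeled table is empty")
    if ANOMALY_COLUMN not in labeled.columns:
        raise ValueError(f"table lacks the {ANOMALY_COLUMN!r} column")
    cols = FIDUCIAL_COLUMNS + [ANOMALY_COLUMN]
    means = {}
    for name, label in (("Anomalous Means", -1), ("Normal Means", 1)):
        group = labeled.loc[labeled[ANOMALY_COLUMN] == label, cols]
        means[name] = group.mean() if len(group) else pd.Series(np.nan, index=cols)
    return pd.DataFrame(means, index=cols)


@dataclass(frozen=True)
class AnomalyMetrics:
    accuracy: float
    tpr: float
    fpr: float


def evaluate_against_truth(labeled: pd.DataFrame, truth_rows) -> AnomalyMetrics:
    """Confusion-matrix metrics with anomalous (-1) as the positive class.

    ``truth_rows`` are the positions of the truly anomalous rows. TPR (or
    FPR) is NaN when there are no true positives (negatives) to detect.
    """
    n = len(labeled)
    truth_rows = np.asarray(sorted(truth_rows), dtype=int)
    if len(truth_rows) and (truth_rows.min() < 0 or truth_rows.max() >= n):
        raise ValueError("truth indices outside the table")
    is_pos = np.zeros(n, dtype=bool)
    is_pos[truth_rows] = True
    pred_pos = labeled[ANOMALY_COLUMN].to_numpy() == -1
    tp = int(np.sum(pred_pos & is_pos))
    fp = int(np.sum(pred_pos & ~is_pos))
    tn = int(np.sum(~pred_pos & ~is_pos))
    fn = int(np.sum(~pred_pos & is_pos))
    acc = (tp + tn) / n
    tpr = tp / (tp + fn) if (tp + fn) else float("nan")
    fpr = fp / (fp + tn) if (fp + tn) else float("nan")
    return AnomalyMetrics(accuracy=acc, tpr=tpr, fpr=fpr)
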
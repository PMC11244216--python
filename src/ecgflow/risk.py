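"""Tabular cardiac-risk analysis: scaling, correlation, distribution
summaries, and a six-family classifier comparison.

The patient table carries nine features (age, sex, chest pain, blood
pressure, cholesterol, alcohol, diabetes, ECG change, smoking) and a binary
condition outcome. The comparison fits logistic regression, a decision
tree, a random forest, an RBF support-vector machine, gradient-boosted
trees (XGBoost), and a small 1-D convolutional network over repeated
stratified train/test splits, reporting accuracy and F1 per split. Feature
scaling (z-score) is fit on each training fold only, so no test-fold
statistics leak into the models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, f1_score
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .nn import Conv1DClassifier
from .synthetic import PATIENT_COLUMNS

TARGET_COLUMN = "Condition"
FEATURE_COLUMNS = [c for c in PATIENT_COLUMNS if c != TARGET_COLUMN]

MODEL_NAMES = [
    "logistic_regression",
    "decision_tree",
    "random_forest",
    "svm",
    "xgboost",
    "cnn",
]


def validate_patient_table(table: pd.DataFrame) -> None:
    """Raise on schema violations: missing columns, NaNs, non-binary flags."""
    missing = [c for c in PATIENT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"patient table missing columns: {', '.join(missing)}")
    if table[PATIENT_COLUMNS].isna().any().any():
        raise ValueError("patient table contains missing values")
    for col in ("Sex", "Chest Pain", "Alcohol", "Diabetes", "ECG Change", "Smoking", TARGET_COLUMN):
        vals = set(table[col].unique())
        if not vals <= {0, 1}:
            raise ValueError(f"column {col!r} must be binary 0/1, found {sorted(vals)}")
    for col in ("Age", "Blood Pressure", "Cholesterol"):
        if (table[col] <= 0).any():
            raise ValueError(f"column {col!r} must be positive")


def standardize_features(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Z-score the nine feature columns; the condition column is untouched.

    Uses the population standard deviation (ddof=0), matching the scaler
    applied inside the model-comparison folds, so a balanced 0/1 column maps
    exactly to ±1. Returns the scaled feature frame and a parameter frame
    (mean and sd per column) for reuse on held-out data.
    """
    feats = table[FEATURE_COLUMNS].astype(float)
    mean = feats.mean()
    sd = feats.std(ddof=0)
    zero = sd[sd == 0]
    if len(zero):
        raise ValueError(f"zero-variance feature column(s): {', '.join(zero.index)}")
    scaled = (feats - mean) / sd
    params = pd.DataFrame({"mean": mean, "sd": sd})
    return scaled, params


def correlation_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation over all ten columns (features + condition).

    Symmetric with unit diagonal; entries involving a constant column are
    NaN (undefined), never coerced to a number.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 rows for a correlation matrix")
    return table[PATIENT_COLUMNS].astype(float).corr(method="pearson")


@dataclass(frozen=True)
class BoxSummary:
    """Five-number summary with 1.5-IQR outlier fences for one group."""

    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float
    outliers: tuple

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def boxplot_summary(table: pd.DataFrame, by: str = TARGET_COLUMN) -> dict:
    """Per-variable five-number summaries within each outcome group.

    Quartiles use linear interpolation. Outliers are values beyond
    ``Q1 - 1.5 IQR`` or ``Q3 + 1.5 IQR``. Keys are ``(variable, group)``.
    """
    groups = sorted(table[by].unique())
    if len(groups) < 2:
        raise ValueError(f"column {by!r} has a single group; nothing to compare")
    out: dict[tuple[str, int], BoxSummary] = {}
    for g in groups:
        sub = table.loc[table[by] == g]
        for col in FEATURE_COLUMNS:
            v = sub[col].to_numpy(dtype=float)
            q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
            iqr = q3 - q1
            lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
            outliers = tuple(sorted(v[(v < lo_fence) | (v > hi_fence)]))
            out[(col, g)] = BoxSummary(
                minimum=float(v.min()), q1=float(q1), median=float(med),
                q3=float(q3), maximum=float(v.max()), outliers=outliers,
            )
    return out


def default_models(seed: int = 0) -> dict:
    """Fresh instances of the six default classifier families."""
    return {
        "logistic_regression": LogisticRegression(max_iter=1000),
        "decision_tree": DecisionTreeClassifier(random_state=seed),
        "random_forest": RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1),
        "svm": SVC(kernel="rbf", C=1.0),
        "xgboost": XGBClassifier(
            n_estimators=100, max_depth=3, learning_rate=0.3,
            eval_metric="logloss", random_state=seed, n_jobs=1, verbosity=0,
        ),
        "cnn": Conv1DClassifier(seed=seed),
    }


@dataclass(frozen=True)
class ModelReport:
    """Per-split accuracy/F1 for each model plus the split configuration."""

    results: pd.DataFrame  # columns: model, split, accuracy, f1
    repeats: int
    test_fraction: float
    seed: int
    model_names: tuple = field(default_factory=tuple)

    def summary(self) -> pd.DataFrame:
        """Mean and standard deviation of both metrics per model."""
        agg = self.results.groupby("model")[["accuracy", "f1"]].agg(["mean", "std"])
        agg.columns = ["_".join(c) for c in agg.columns]
        return agg.reindex(list(self.model_names))

    def mean_accuracy(self, model: str) -> float:
        return float(self.results.loc[self.results["model"] == model, "accuracy"].mean())

    def mean_f1(self, model: str) -> float:
        return float(self.results.loc[self.results["model"] == model, "f1"].mean())


def evaluate_models(
    table: pd.DataFrame,
    models: dict | None = None,
    repeats: int = 50,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> ModelReport:
    """Repeated stratified train/test comparison of the classifier set.

    For each of ``repeats`` random stratified splits, a fresh z-score scaler
    and fresh model instances are fit on the training fold only; accuracy
    and F1 are recorded on the test fold. F1 with no predicted and no true
    positives is reported as 0 with a warning (a documented convention, not
    an error).
    """
    validate_patient_table(table)
    if models is None:
        models = default_models(seed=seed)
    y = table[TARGET_COLUMN].to_numpy(dtype=int)
    x = table[FEATURE_COLUMNS].to_numpy(dtype=float)
    if np.bincount(y, minlength=2).min() < 2:
        raise ValueError("each outcome class needs at least 2 members for stratified splits")
    splitter = StratifiedShuffleSplit(
        n_splits=repeats, test_size=test_fraction, random_state=seed
    )
    rows = []
    for split_id, (tr, te) in enumerate(splitter.split(x, y)):
        if len(np.unique(y[te])) < 2:
            warnings.warn(f"split {split_id}: single-class test fold", stacklevel=2)
        scaler = StandardScaler().fit(x[tr])
        xtr, xte = scaler.transform(x[tr]), scaler.transform(x[te])
        for name, proto in models.items():
            model = _clone(proto)
            model.fit(xtr, y[tr])
            pred = np.asarray(model.predict(xte)).astype(int)
            rows.append(
                {
                    "model": name,
                    "split": split_id,
                    "accuracy": accuracy_score(y[te], pred),
                    "f1": f1_score(y[te], pred, zero_division=0),
                }
            )
    results = pd.DataFrame(rows)
    return ModelReport(
        results=results,
        repeats=repeats,
        test_fraction=test_fraction,
        seed=seed,
        model_names=tuple(models),
    )


def _clone(model):
    """Fresh unfitted copy of an estimator via its constructor parameters."""
    return type(model)(**model.get_params())
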
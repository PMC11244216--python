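"""Feature scaling, correlation, boxplot summaries, model comparison."""

import math

import numpy as np
import pandas as pd
import pytest

from ecgflow import (
    CohortMarginals,
    Conv1DClassifier,
    PATIENT_COLUMNS,
    boxplot_summary,
    correlation_matrix,
    evaluate_models,
    generate_patient_table,
    standardize_features,
)
from ecgflow.risk import FEATURE_COLUMNS, MODEL_NAMES

# worked 11-patient example in the published table schema
EXAMPLE_ROWS = [
    [35, 1, 1, 120, 198, 1, 0, 1, 1, 1],
    [35, 1, 1, 126, 282, 1, 1, 1, 0, 1],
    [42, 1, 1, 136, 315, 1, 0, 1, 1, 1],
    [48, 1, 1, 124, 274, 0, 1, 0, 1, 1],
    [44, 1, 1, 120, 169, 1, 1, 1, 1, 1],
    [28, 1, 1, 104, 208, 0, 0, 1, 1, 0],
    [45, 0, 1, 138, 236, 0, 0, 1, 1, 0],
    [47, 1, 1, 112, 204, 0, 0, 0, 0, 0],
    [30, 0, 1, 138, 243, 0, 0, 1, 1, 0],
    [46, 1, 1, 140, 311, 0, 0, 1, 1, 1],
    [53, 1, 1, 140, 203, 1, 1, 1, 1, 1],
]


@pytest.fixture()
def example_table():
    return pd.DataFrame(EXAMPLE_ROWS, columns=PATIENT_COLUMNS)


@pytest.fixture(scope="module")
def cohort():
    return generate_patient_table(200, seed=0)


class TestStandardize:
    def test_columns_have_mean_zero_sd_one(self, cohort):
        scaled, _ = standardize_features(cohort)
        np.testing.assert_allclose(scaled.mean(), 0.0, atol=1e-9)
        np.testing.assert_allclose(scaled.std(ddof=0), 1.0, atol=1e-9)

    def test_idempotent_within_tolerance(self, cohort):
        scaled, _ = standardize_features(cohort)
        again = cohort.copy()
        again[FEATURE_COLUMNS] = scaled
        twice, _ = standardize_features(again)
        np.testing.assert_allclose(twice.to_numpy(), scaled.to_numpy(), atol=1e-9)

    def test_balanced_binary_maps_to_plus_minus_one(self):
        table = pd.DataFrame(
            [
                [30, 0, 0, 110, 180, 0, 0, 0, 0, 0],
                [40, 1, 1, 120, 200, 1, 1, 1, 1, 1],
                [50, 0, 1, 130, 220, 0, 1, 0, 0, 0],
                [60, 1, 0, 140, 240, 1, 0, 1, 1, 1],
            ],
            columns=PATIENT_COLUMNS,
        )
        scaled, _ = standardize_features(table)
        assert sorted(scaled["Smoking"].unique()) == [-1.0, 1.0]

    def test_zero_variance_column_named_in_error(self, example_table):
        with pytest.raises(ValueError, match="Chest Pain"):
            standardize_features(example_table)  # chest pain is constant here

    def test_parameters_reproduce_scaling(self, cohort):
        scaled, params = standardize_features(cohort)
        manual = (cohort[FEATURE_COLUMNS] - params["mean"]) / params["sd"]
        np.testing.assert_allclose(manual.to_numpy(), scaled.to_numpy())


class TestCorrelation:
    def test_symmetric_unit_diagonal(self, cohort):
        c = correlation_matrix(cohort)
        assert c.shape == (10, 10)
        np.testing.assert_allclose(np.diag(c), 1.0)
        np.testing.assert_allclose(c.to_numpy(), c.to_numpy().T, atol=1e-12)

    def test_example_smoking_condition_matches_hand_pearson(self, example_table):
        c = correlation_matrix(example_table)
        x = np.array([r[8] for r in EXAMPLE_ROWS], dtype=float)  # smoking
        y = np.array([r[9] for r in EXAMPLE_ROWS], dtype=float)  # condition
        n = len(x)
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        hand = sxy / math.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert c.loc["Smoking", "Condition"] == pytest.approx(hand)
        assert n == 11

    def test_constant_column_gives_nan_not_zero(self, example_table):
        c = correlation_matrix(example_table)
        assert np.isnan(c.loc["Chest Pain", "Age"])

    def test_too_few_rows_rejected(self, example_table):
        with pytest.raises(ValueError):
            correlation_matrix(example_table.iloc[:2])


class TestBoxplot:
    def test_hand_quartiles_linear_interpolation(self, cohort):
        table = cohort.iloc[:10].copy()
        table["Condition"] = [0] * 5 + [1] * 5
        table.loc[table.index[:5], "Age"] = [1, 2, 3, 4, 5]
        out = boxplot_summary(table)
        s = out[("Age", 0)]
        assert (s.q1, s.median, s.q3) == (2.0, 3.0, 4.0)
        assert s.minimum == 1.0 and s.maximum == 5.0

    def test_all_equal_group_has_no_outliers(self, cohort):
        table = cohort.iloc[:8].copy()
        table["Condition"] = [0] * 4 + [1] * 4
        table.loc[table.index[:4], "Cholesterol"] = 200.0
        s = boxplot_summary(table)[("Cholesterol", 0)]
        assert s.iqr == 0.0 and s.outliers == ()

    def test_extreme_value_flagged_as_outlier(self, cohort):
        table = cohort.iloc[:12].copy()
        table["Condition"] = [0] * 6 + [1] * 6
        table.loc[table.index[:6], "Blood Pressure"] = [120, 121, 122, 123, 124, 9000]
        s = boxplot_summary(table)[("Blood Pressure", 0)]
        assert 9000.0 in s.outliers

    def test_single_group_rejected(self, cohort):
        table = cohort.copy()
        table["Condition"] = 1
        with pytest.raises(ValueError):
            boxplot_summary(table)


class TestEvaluateModels:
    def test_report_contains_six_default_families(self, cohort):
        report = evaluate_models(cohort, repeats=2, seed=0)
        assert sorted(report.model_names) == sorted(MODEL_NAMES)
        assert len(report.results) == 6 * 2
        assert report.results["accuracy"].between(0, 1).all()
        assert report.results["f1"].between(0, 1).all()

    def test_fixed_seed_reproducible(self, cohort):
        a = evaluate_models(cohort, repeats=2, seed=3)
        b = evaluate_models(cohort, repeats=2, seed=3)
        pd.testing.assert_frame_equal(a.results, b.results)

    def test_separable_cohort_all_models_accurate(self):
        table = generate_patient_table(300, CohortMarginals().separable(), seed=5)
        report = evaluate_models(table, repeats=5, seed=5)
        for name in MODEL_NAMES:
            assert report.mean_accuracy(name) >= 0.95, name

    def test_scaler_fit_on_training_fold_only(self, cohort):
        """A spy model sees training features scaled by train-fold stats alone."""
        from sklearn.model_selection import StratifiedShuffleSplit

        seen = []

        class Spy:
            def get_params(self):
                return {}

            def fit(self, x, y):
                seen.append(x.copy())
                return self

            def predict(self, x):
                return np.zeros(len(x), dtype=int)

        evaluate_models(cohort, models={"spy": Spy()}, repeats=2, seed=9)
        x = cohort[FEATURE_COLUMNS].to_numpy(dtype=float)
        y = cohort["Condition"].to_numpy()
        splits = StratifiedShuffleSplit(n_splits=2, test_size=0.2, random_state=9)
        for got, (tr, _) in zip(seen, splits.split(x, y)):
            expected = (x[tr] - x[tr].mean(axis=0)) / x[tr].std(axis=0)
            np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_single_class_table_rejected(self, cohort):
        table = cohort.copy()
        table["Condition"] = 1
        with pytest.raises(ValueError):
            evaluate_models(table, repeats=1)


class TestConvNet:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(60, 9))
        y = (x[:, 0] + x[:, 3] > 0).astype(int)
        a = Conv1DClassifier(seed=4, epochs=100).fit(x, y).predict_proba(x)
        b = Conv1DClassifier(seed=4, epochs=100).fit(x, y).predict_proba(x)
        np.testing.assert_array_equal(a, b)

    def test_learns_linear_rule(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(200, 9))
        y = (x[:, 2] - x[:, 6] > 0.0).astype(int)
        model = Conv1DClassifier(seed=0).fit(x[:150], y[:150])
        assert (model.predict(x[150:]) == y[150:]).mean() >= 0.9

    def test_too_few_features_rejected(self):
        with pytest.raises(ValueError):
            Conv1DClassifier().fit(np.zeros((10, 2)), np.zeros(10))
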
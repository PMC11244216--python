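"""Synthetic ECG and cohort generators: determinism, symmetry, marginals."""

import numpy as np
import pandas as pd
import pytest

from ecgflow import (
    FIDUCIAL_COLUMNS,
    BeatTemplate,
    CohortMarginals,
    PATIENT_COLUMNS,
    SynthConfig,
    generate_ecg,
    generate_patient_table,
    inject_fiducial_outliers,
)
from ecgflow.fiducials import TEMPORAL_ORDER


class TestGenerateEcg:
    def test_inversion_is_exact_negation(self):
        a, _ = generate_ecg(SynthConfig(seed=9))
        b, gt = generate_ecg(SynthConfig(seed=9, inverted=True))
        np.testing.assert_array_equal(a.samples, -b.samples)
        assert gt.inverted

    def test_signal_length_matches_config(self):
        sig, _ = generate_ecg(SynthConfig(fs=360, duration=7.5, seed=0))
        assert len(sig) == round(360 * 7.5)

    def test_r_spacing_at_60_bpm(self):
        _, gt = generate_ecg(SynthConfig(heart_rate=60, duration=10, fs=360, seed=4))
        diffs = np.diff(gt.column("R"))
        # 1 s period at 360 Hz, +/- 2% jitter (and 1-sample extremum quantization)
        assert np.all(np.abs(diffs - 360) <= 360 * 0.02 + 1)

    def test_clean_r_truth_is_beat_argmax(self):
        sig, gt = generate_ecg(SynthConfig(seed=2).clean())
        r = gt.column("R")
        half = int(np.diff(r).mean() // 2)
        for ri in r:
            lo, hi = max(0, ri - half), min(len(sig), ri + half)
            assert lo + np.argmax(sig.samples[lo:hi]) == ri

    @pytest.mark.parametrize("bpm", [40, 75, 120, 180])
    def test_ground_truth_ordering_and_bounds(self, bpm):
        sig, gt = generate_ecg(SynthConfig(heart_rate=bpm, seed=bpm))
        arr = gt.table[TEMPORAL_ORDER].to_numpy()
        assert np.all(np.diff(arr, axis=1) > 0)
        assert arr.min() >= 0 and arr.max() < len(sig)

    def test_seeded_reproducibility(self):
        a, ga = generate_ecg(SynthConfig(seed=5))
        b, gb = generate_ecg(SynthConfig(seed=5))
        np.testing.assert_array_equal(a.samples, b.samples)
        pd.testing.assert_frame_equal(ga.table, gb.table)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"fs": -1.0},
            {"duration": 0.0},
            {"heart_rate": 10.0},
            {"heart_rate": 300.0},
            {"white_sd": -0.1},
            {"mains_freq": 55.0},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SynthConfig(**kwargs)

    def test_template_invariants_enforced(self):
        with pytest.raises(ValueError):
            BeatTemplate(offsets={"P": -0.1, "Q": -0.2, "R": 0.0, "S": 0.04, "T": 0.2})
        with pytest.raises(ValueError):
            BeatTemplate(amplitudes={"P": 0.1, "Q": 0.1, "R": 1.0, "S": -0.2, "T": 0.3})


class TestGeneratePatientTable:
    def test_schema_is_exact_header(self):
        t = generate_patient_table(20, seed=0)
        assert list(t.columns) == PATIENT_COLUMNS

    def test_same_seed_identical(self):
        pd.testing.assert_frame_equal(
            generate_patient_table(132, seed=7), generate_patient_table(132, seed=7)
        )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_smoking_rate_within_3_binomial_sd(self, seed):
        t = generate_patient_table(132, seed=seed)
        rate = CohortMarginals().smoking
        sd = np.sqrt(rate * (1 - rate) / 132)
        assert abs(t["Smoking"].mean() - rate) <= 3 * sd

    def test_blood_pressure_mean_at_scale(self):
        m = CohortMarginals()
        t = generate_patient_table(10_000, m, seed=1)
        sd = m.bp_sd / np.sqrt(10_000)
        assert abs(t["Blood Pressure"].mean() - m.bp_mean) <= 3 * sd

    def test_continuous_columns_within_ranges(self):
        m = CohortMarginals()
        t = generate_patient_table(2000, m, seed=3)
        assert t["Age"].between(*m.age_range).all()
        assert t["Blood Pressure"].between(*m.bp_range).all()
        assert t["Cholesterol"].between(*m.chol_range).all()

    def test_binary_columns_are_binary(self):
        t = generate_patient_table(500, seed=2)
        for col in ("Sex", "Chest Pain", "Alcohol", "Diabetes", "ECG Change", "Smoking", "Condition"):
            assert set(t[col].unique()) <= {0, 1}

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            CohortMarginals(alcohol=1.3)
        with pytest.raises(ValueError):
            generate_patient_table(0)

    def test_separable_margin_rule_is_deterministic_threshold(self):
        from ecgflow.synthetic import _cohort_logit

        m = CohortMarginals().separable()
        t = generate_patient_table(300, m, seed=4)
        z = _cohort_logit(t, m)
        assert np.all(np.abs(z) >= m.margin)
        np.testing.assert_array_equal(t["Condition"].to_numpy(), (z > 0).astype(int))


class TestInjectOutliers:
    @pytest.fixture()
    def base_table(self):
        _, gt = generate_ecg(SynthConfig(duration=30, seed=6).clean())
        return gt.table

    def test_k_zero_is_identity(self, base_table):
        out, rows = inject_fiducial_outliers(base_table, 0, 100.0, seed=0)
        pd.testing.assert_frame_equal(out, base_table)
        assert len(rows) == 0

    def test_k_equals_rows_perturbs_everything(self, base_table):
        out, rows = inject_fiducial_outliers(base_table, len(base_table), 50.0, seed=1)
        assert len(rows) == len(base_table)
        assert (out[FIDUCIAL_COLUMNS] != base_table[FIDUCIAL_COLUMNS]).all().all()

    def test_unperturbed_rows_bit_identical(self, base_table):
        out, rows = inject_fiducial_outliers(base_table, 3, 500.0, seed=2)
        keep = np.setdiff1d(np.arange(len(base_table)), rows)
        pd.testing.assert_frame_equal(out.iloc[keep], base_table.iloc[keep])

    def test_k_beyond_rows_rejected(self, base_table):
        with pytest.raises(ValueError):
            inject_fiducial_outliers(base_table, len(base_table) + 1, 10.0)

    def test_perturbed_row_breaks_r_trend(self, base_table):
        """A 10x inter-beat-spread offset must stick out >5x the residual sd."""
        r = base_table["R_Peaks"].to_numpy(dtype=float)
        idx = np.arange(len(r))
        coef = np.polyfit(idx, r, 1)
        resid_sd = np.std(r - np.polyval(coef, idx))
        magnitude = 10 * np.std(np.diff(r))
        out, rows = inject_fiducial_outliers(base_table, 1, magnitude, seed=3)
        row = rows[0]
        new_resid = out["R_Peaks"].iloc[row] - np.polyval(coef, row)
        assert abs(new_resid) > 5 * resid_sd
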
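"""Cleaning, bucketing, covariate extension and encoding contracts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from survtv import (
    bucket_continuous,
    clean_records,
    encode_dataset,
    extend_covariates,
    load_code_maps,
)
from conftest import build_cohort, make_patient, make_visit


class TestCodeMaps:
    def test_fixture_cardinalities(self):
        maps = load_code_maps()
        assert set(maps.ae_map["category_index"]) == set(range(1, 19))
        counts = maps.drug_map["drug_class"].value_counts()
        assert counts["chemotherapy"] == 82
        assert counts["biotherapy"] == 49
        assert counts["hormone"] == 10
        assert len(maps.drug_map) == 141

    def test_lookup(self):
        maps = load_code_maps()
        code = maps.drug_map["hcpcs_code"].iloc[0]
        assert maps.drug_class(code) == "chemotherapy"
        with pytest.raises(KeyError):
            maps.ae_category("nope")


class TestCleanRecords:
    def test_exact_duplicate_collapsed(self, toy_cohort):
        dup = toy_cohort.visits.iloc[[1]]
        toy_cohort.visits = pd.concat([toy_cohort.visits, dup], ignore_index=True)
        clean, report = clean_records(toy_cohort)
        assert report["duplicate_visits"] == 1
        assert len(clean.visits) == 8

    def test_duplicate_union_of_flags(self, toy_cohort):
        extra = make_visit("A", 2, bio=1, aes=(5,), comorb=4.0)
        toy_cohort.visits = pd.concat(
            [toy_cohort.visits, pd.DataFrame([extra])], ignore_index=True
        )
        clean, _ = clean_records(toy_cohort)
        row = clean.visits.query("patient_id == 'A' and month == 2").iloc[0]
        assert row["treat_chemo"] == 1 and row["treat_bio"] == 1
        assert row["ae_05"] == 1
        assert row["comorbidity_index"] == 4.0  # last value wins

    def test_idempotent(self, toy_cohort):
        once, _ = clean_records(toy_cohort)
        twice, report = clean_records(once)
        assert sum(report.values()) == 0
        pd.testing.assert_frame_equal(once.visits, twice.visits)
        pd.testing.assert_frame_equal(once.patients, twice.patients)

    def test_out_of_window_and_invalid_dropped(self):
        """5-row toy, enumerated by hand: patient X (diagnosis 0, duration 4)
        has visits at months 0, 3, 6 -> the month-6 visit is out of window;
        patient Y has a negative duration -> patient and its 2 visits drop."""
        patients = [
            make_patient("X", diagnosis=0, duration=4),
            make_patient("Y", diagnosis=0, duration=-1),
        ]
        visits = [
            make_visit("X", 0), make_visit("X", 3), make_visit("X", 6),
            make_visit("Y", 0), make_visit("Y", 1),
        ]
        clean, report = clean_records(build_cohort(patients, visits))
        assert report["invalid_patients"] == 1
        assert report["out_of_window_visits"] == 1
        assert list(clean.patients["patient_id"]) == ["X"]
        assert list(clean.visits["month"]) == [0, 3]


class TestBucketContinuous:
    def test_direct_and_boundary(self):
        bounds = (65, 70, 75, 80, 85)
        assert bucket_continuous(76, bounds) == 2   # [75, 80)
        assert bucket_continuous(80, bounds) == 3   # half-open: goes right
        assert bucket_continuous(60, bounds) == 0
        assert bucket_continuous(99, bounds) == 4

    def test_empty_boundaries_rejected(self):
        with pytest.raises(ValueError):
            bucket_continuous(1.0, ())

    def test_against_linear_scan_oracle(self):
        rng = np.random.default_rng(0)
        bounds = np.sort(rng.choice(np.arange(100), size=7, replace=False)).astype(float)
        values = rng.uniform(-10, 110, size=1000)

        def scan(v):
            if v < bounds[0]:
                return 0
            for i in range(len(bounds) - 1):
                if bounds[i] <= v < bounds[i + 1]:
                    return i
            return len(bounds) - 1

        got = bucket_continuous(values, bounds)
        assert np.array_equal(got, [scan(v) for v in values])


class TestExtendCovariates:
    def test_no_visits_yet_gives_zero_history(self, toy_cohort):
        # patient B diagnosed at month 5 has its first visit at month 5;
        # drop it to query a patient with an empty history
        toy_cohort.visits = toy_cohort.visits[toy_cohort.visits["patient_id"] != "B"]
        vec = extend_covariates(toy_cohort, "B", 6)
        d = vec.as_dict()
        assert all(d[f"cum_{t}"] == 0 for t in ("chemo", "bio", "hormone"))
        assert d["months_since_last_treatment"] == -1.0
        assert d["months_since_diagnosis"] == 1.0
        assert d["comorbidity_bucket"] == bucket_continuous(0.0, (0, 1, 2, 3, 5, 8))

    def test_hand_accumulated_history(self, toy_cohort):
        # A: chemo at months 2 and 5, AE category 3 at month 5
        vec = extend_covariates(toy_cohort, "A", 6)
        d = vec.as_dict()
        assert d["cum_chemo"] == 2
        assert d["cum_ae_03"] == 1
        assert d["months_since_last_treatment"] == 1.0
        assert d["comorbidity_bucket"] == bucket_continuous(3.0, (0, 1, 2, 3, 5, 8))

    def test_no_lookahead(self, toy_cohort):
        vec = extend_covariates(toy_cohort, "A", 4)
        d = vec.as_dict()
        assert d["cum_chemo"] == 1
        assert d["cum_ae_03"] == 0
        # perturbing a later visit leaves the vector unchanged
        perturbed = toy_cohort
        perturbed.visits.loc[
            (perturbed.visits["patient_id"] == "A") & (perturbed.visits["month"] == 5),
            "treat_bio",
        ] = 1
        vec2 = extend_covariates(perturbed, "A", 4)
        assert np.array_equal(vec.values, vec2.values)

    def test_errors(self, toy_cohort):
        with pytest.raises(KeyError):
            extend_covariates(toy_cohort, "ZZ", 3)
        with pytest.raises(ValueError):
            extend_covariates(toy_cohort, "B", 2)  # before diagnosis at 5


class TestEncodeDataset:
    def test_fixed_only_shape(self, toy_cohort):
        ds = encode_dataset(toy_cohort, "fixed_only")
        assert len(ds) == 3
        assert "cum_chemo" not in ds.feature_names
        assert np.array_equal(ds.durations, [8, 12, 20])

    def test_extended_row_count_by_enumeration(self, toy_cohort):
        # 3 + 1 + 4 visits -> 8 landmark rows
        ds = encode_dataset(toy_cohort, "extended")
        assert len(ds) == 8
        last = encode_dataset(toy_cohort, "extended", landmark_policy="last")
        assert len(last) == 3

    def test_extended_rows_match_pointwise_extension(self, toy_cohort):
        """Every vectorised landmark row equals the per-patient reference
        implementation at the same month."""
        ds = encode_dataset(toy_cohort, "extended")
        for i in range(len(ds)):
            vec = extend_covariates(toy_cohort, ds.patient_ids[i], ds.landmark_months[i])
            assert np.allclose(ds.features[i], vec.values), (ds.patient_ids[i], i)

    def test_residual_durations(self, toy_cohort):
        ds = encode_dataset(toy_cohort, "extended")
        a = ds.patient_ids == "A"
        # A: diagnosis 0, duration 8, visits at 0, 2, 5
        assert np.array_equal(ds.durations[a], [8, 6, 3])

    def test_first_landmark_matches_fixed_block(self, toy_cohort):
        fixed = encode_dataset(toy_cohort, "fixed_only")
        ext = encode_dataset(toy_cohort, "extended")
        n_fixed = len(fixed.feature_names)
        for pid in fixed.patient_ids:
            rows = np.flatnonzero(ext.patient_ids == pid)
            first = rows[np.argmin(ext.landmark_months[rows])]
            np.testing.assert_array_equal(
                ext.features[first, :n_fixed],
                fixed.features[fixed.patient_ids == pid][0],
            )

    def test_standardization(self, small_cohort):
        clean, _ = clean_records(small_cohort)
        ds = encode_dataset(clean, "extended").fit_standardizer()
        assert np.all(np.isfinite(ds.features))
        assert np.allclose(ds.features.mean(axis=0), 0.0, atol=1e-9)
        stds = ds.features.std(axis=0)
        assert np.allclose(stds[stds > 0], 1.0, atol=1e-9)

    def test_unknown_mode_rejected(self, toy_cohort):
        with pytest.raises(ValueError):
            encode_dataset(toy_cohort, "bogus")


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_encoded_features_always_finite(seed):
    """Random small cohorts always encode to finite numeric matrices."""
    from survtv import GeneratorConfig, generate_cohort

    cohort = generate_cohort(GeneratorConfig(n_patients=8, seed=seed, horizon_months=60))
    for mode in ("fixed_only", "extended"):
        ds = encode_dataset(cohort, mode)
        assert np.all(np.isfinite(ds.features))
        assert np.all(ds.durations >= 0)
        assert set(np.unique(ds.events)) <= {0, 1}
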
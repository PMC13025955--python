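"""Labels, featurizer, summaries, resampling and split contracts."""

import numpy as np
import pandas as pd
import pytest

from medhg import cohort_features as cf


def _enc_frame(los, death=None, ids=None):
    n = len(los)
    return pd.DataFrame({
        "encounter_id": ids or [f"e{i}" for i in range(n)],
        "patient_id": [f"p{i}" for i in range(n)],
        "postop_los": los,
        "death_offset": death if death is not None else [np.nan] * n,
    })


class TestDeriveOutcomes:
    def test_quantile_threshold_by_sorting_oracle(self):
        """LOS {1..8} at q=0.75 gives the interpolated threshold 6.25, so
        7 is prolonged and 6 is not."""
        enc = _enc_frame([1, 2, 3, 4, 5, 6, 7, 8])
        labels = cf.derive_outcomes(enc)
        assert labels["plos_threshold_days"].iloc[0] == pytest.approx(6.25)
        by_id = labels.set_index("encounter_id")["plos"]
        assert by_id["e6"] == 1 and by_id["e5"] == 0  # los 7 vs los 6

    def test_mortality_boundaries_inclusive_and_nested(self):
        enc = _enc_frame([1, 1, 1, 1], death=[30.0, 31.0, 90.0, np.nan])
        lab = cf.derive_outcomes(enc)
        assert lab["mort30"].tolist() == [1, 0, 0, 0]
        assert lab["mort90"].tolist() == [1, 1, 1, 0]
        assert ((lab["mort30"] <= lab["mort90"]).all())

    def test_reference_rows_restrict_threshold(self):
        enc = _enc_frame([1, 2, 3, 100])
        lab = cf.derive_outcomes(enc, reference_rows=["e0", "e1", "e2"])
        assert lab["plos_threshold_days"].iloc[0] == pytest.approx(2.5)
        with pytest.raises(ValueError):
            cf.derive_outcomes(enc, reference_rows=[])

    def test_threshold_property_bounded_exceedance(self, small_cohort):
        _, enc, _, _ = small_cohort
        lab = cf.derive_outcomes(enc)
        frac = lab["plos"].mean()
        assert frac <= 0.25 + 1.0 / len(enc)


class TestFeaturizer:
    def test_mean_imputation_and_population_sd_standardization(self):
        """{1,2,3,missing} -> impute 2, standardize to {-1.2247, 0, 1.2247, 0}."""
        enc = pd.DataFrame({"encounter_id": list("abcd"),
                            "cci": [1.0, 2.0, 3.0, np.nan]})
        fz = cf.EncounterFeaturizer(continuous=("cci",), categorical=(),
                                    binary=())
        out = fz.fit(enc).transform(enc)
        np.testing.assert_allclose(out["cci"].to_numpy(),
                                   [-1.224745, 0.0, 1.224745, 0.0], atol=1e-5)

    def test_onehot_with_unknown_level_sums_to_one(self):
        enc = pd.DataFrame({"encounter_id": list("abc"),
                            "sex": ["A", "B", np.nan]})
        fz = cf.EncounterFeaturizer(continuous=(), categorical=("sex",), binary=())
        out = fz.fit(enc).transform(enc)
        assert set(out.columns) == {"sex=A", "sex=B", "sex=Unknown"}
        np.testing.assert_allclose(out.sum(axis=1).to_numpy(), 1.0)
        # unseen level maps to Unknown
        new = fz.transform(pd.DataFrame({"encounter_id": ["z"], "sex": ["C"]}))
        assert new["sex=Unknown"].iloc[0] == 1.0

    def test_all_missing_column_dropped_with_warning(self):
        enc = pd.DataFrame({"encounter_id": list("ab"),
                            "cci": [np.nan, np.nan], "age": [40.0, 60.0]})
        fz = cf.EncounterFeaturizer(continuous=("cci", "age"), categorical=(),
                                    binary=())
        with pytest.warns(UserWarning, match="cci"):
            fz.fit(enc)
        assert "cci" in fz.dropped_ and "age" in fz.means_

    def test_zero_variance_column_dropped(self):
        enc = pd.DataFrame({"encounter_id": list("abc"), "age": [50.0] * 3})
        fz = cf.EncounterFeaturizer(continuous=("age",), categorical=(), binary=())
        with pytest.warns(UserWarning, match="zero variance"):
            fz.fit(enc)
        assert fz.feature_names_ == []

    def test_plausibility_ranges_null_out_outliers(self):
        enc = pd.DataFrame({"encounter_id": list("abcd"),
                            "bmi": [25.0, 30.0, 500.0, 35.0]})
        fz = cf.EncounterFeaturizer(continuous=("bmi",), categorical=(), binary=())
        fz.fit(enc)
        assert fz.means_["bmi"] == pytest.approx(30.0)  # 500 excluded

    def test_training_rows_only_no_leakage(self, small_cohort):
        """Fitted statistics are invariant to arbitrary changes confined to
        non-training rows."""
        _, enc, _, _ = small_cohort
        splits = cf.split_indices(enc, seed=0)
        _, fz1 = cf.build_feature_matrix(enc, splits.train)
        corrupted = enc.copy()
        mask = corrupted["encounter_id"].isin(splits.test)
        corrupted.loc[mask, "age"] = 999.0
        corrupted.loc[mask, "sex"] = "garbled"
        _, fz2 = cf.build_feature_matrix(corrupted, splits.train)
        assert fz1.fitted_stats() == fz2.fitted_stats()

    def test_transform_after_masking_leaves_no_missing(self, small_cohort):
        _, enc, _, _ = small_cohort
        masked = cf.mask_features(enc, {"bmi": 0.3, "cci": 0.3}, seed=1)
        matrix, _ = cf.build_feature_matrix(masked,
                                            masked["encounter_id"].tolist())
        assert not matrix.isna().any().any()
        groups = {}
        for col in matrix.columns:
            if "=" in col:
                groups.setdefault(col.split("=")[0], []).append(col)
        for cols in groups.values():
            np.testing.assert_allclose(matrix[cols].sum(axis=1).to_numpy(), 1.0)


class TestCohortSummary:
    def test_percent_rounding_convention(self):
        assert cf.percent(1, 3) == 33.33
        assert cf.percent(0, 10) == 0.0

    def test_patient_vs_encounter_granularity(self):
        enc = pd.DataFrame({
            "encounter_id": ["e1", "e2", "e3"],
            "patient_id": ["p1", "p1", "p2"],
            "sex": ["female", "female", "male"],
            "race_ethnicity": ["NHW", "NHW", "NHB"],
        })
        labels = pd.DataFrame({"encounter_id": ["e1", "e2", "e3"],
                               "plos": [1, 0, 1], "mort30": [0, 0, 0],
                               "mort90": [0, 0, 1]})
        summary = cf.cohort_summary(enc, labels)
        pat_total = summary.query("level=='patient' and stratum=='total'")
        assert pat_total["count"].iloc[0] == 2  # p1 counted once
        female = summary.query("stratum=='sex' and value=='female'")
        assert female["count"].iloc[0] == 1 and female["percent"].iloc[0] == 50.0
        plos_yes = summary.query("stratum=='plos' and value=='yes'")
        assert plos_yes["count"].iloc[0] == 2
        assert plos_yes["percent"].iloc[0] == 66.67


class TestResample:
    def test_undersample_balances_without_duplicates(self):
        ids = [f"i{k}" for k in range(100)]
        labels = dict(zip(ids, [1] * 10 + [0] * 90))
        out = cf.resample_training(ids, labels, "undersample", seed=0)
        lab = [labels[i] for i in out]
        assert sum(lab) == 10 and len(lab) - sum(lab) == 10
        assert len(set(out)) == len(out)

    def test_oversample_duplicates_positives_to_negative_count(self):
        ids = [f"i{k}" for k in range(100)]
        labels = dict(zip(ids, [1] * 10 + [0] * 90))
        out = cf.resample_training(ids, labels, "oversample", seed=0)
        lab = [labels[i] for i in out]
        assert sum(lab) == 90 and len(lab) - sum(lab) == 90
        assert set(i for i in out if labels[i] == 1) <= set(ids[:10])

    def test_none_mode_is_identity_and_single_class_errors(self):
        ids = ["a", "b"]
        assert cf.resample_training(ids, {"a": 1, "b": 0}, "none", 0) == ids
        with pytest.raises(ValueError):
            cf.resample_training(ids, {"a": 1, "b": 1}, "undersample", 0)

    def test_resample_deterministic(self):
        ids = [f"i{k}" for k in range(50)]
        labels = dict(zip(ids, [1] * 5 + [0] * 45))
        a = cf.resample_training(ids, labels, "oversample", seed=3)
        b = cf.resample_training(ids, labels, "oversample", seed=3)
        assert a == b


class TestSplits:
    def test_ten_encounters_split_8_1_1(self):
        enc = _enc_frame(list(range(10)))
        s = cf.split_indices(enc, seed=0)
        assert (len(s.train), len(s.validation), len(s.test)) == (8, 1, 1)
        assert sorted(s.train + s.validation + s.test) == sorted(enc["encounter_id"])

    def test_patient_grouping_keeps_encounters_together(self):
        enc = pd.DataFrame({"encounter_id": [f"e{i}" for i in range(12)],
                            "patient_id": [f"p{i // 3}" for i in range(12)]})
        s = cf.split_indices(enc, seed=0, group_by="patient")
        pat_of = dict(zip(enc["encounter_id"], enc["patient_id"]))
        for part in (s.train, s.validation, s.test):
            pats = {pat_of[e] for e in part}
            for p in pats:
                members = [e for e, q in pat_of.items() if q == p]
                assert set(members) <= set(part)

    def test_seeds_change_permutation_not_sizes(self):
        enc = _enc_frame(list(range(40)))
        s1 = cf.split_indices(enc, seed=1)
        s2 = cf.split_indices(enc, seed=2)
        assert sorted(map(len, (s1.train, s1.validation, s1.test))) \
            == sorted(map(len, (s2.train, s2.validation, s2.test)))
        assert s1.train != s2.train

    def test_invalid_ratio_and_too_few_groups(self):
        enc = _enc_frame([1, 2])
        with pytest.raises(ValueError):
            cf.split_indices(enc, ratios=(8, 0, 1))
        with pytest.raises(ValueError):
            cf.split_indices(enc, seed=0)  # 2 encounters cannot fill 3 splits
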
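"""Synthetic cohort generator and preprocessing."""

import numpy as np
import pandas as pd
import pytest

import ensemblefs as efs
from ensemblefs.cohort import BIOMARKERS, CohortError


class TestGenerator:
    def test_same_seed_is_bit_identical(self):
        spec = efs.GeneratorSpec(seed=7)
        a, b = efs.generate_cohort(spec), efs.generate_cohort(spec)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self):
        a = efs.generate_cohort(efs.GeneratorSpec(seed=1))
        b = efs.generate_cohort(efs.GeneratorSpec(seed=2))
        assert not a["waist"].equals(b["waist"])

    def test_null_loadings_leave_biomarkers_uncorrelated(self):
        # under all-zero loadings every biomarker is pure noise: sample
        # correlations with both anthropometrics stay near zero
        ok = 0
        for seed in range(20):
            spec = efs.GeneratorSpec(
                n_subjects=2000, effect_total={}, effect_visceral={}, seed=seed
            )
            t = efs.generate_cohort(spec)
            corrs = [
                max(abs(np.corrcoef(t[m], t[c])[0, 1]) for c in ("waist", "bmi"))
                for m in BIOMARKERS
            ]
            ok += max(corrs) < 0.1
        assert ok >= 19

    def test_leptin_tracks_waist_more_than_bmi(self):
        # the visceral-specific marker must correlate more with waist than
        # with BMI — the structure behind the waist/BMI discrimination
        wins = 0
        for seed in range(20):
            t = efs.generate_cohort(efs.GeneratorSpec(n_subjects=2000, seed=seed))
            wins += abs(np.corrcoef(t["leptin"], t["waist"])[0, 1]) > abs(
                np.corrcoef(t["leptin"], t["bmi"])[0, 1]
            )
        assert wins >= 18

    @pytest.mark.parametrize(
        "bad",
        [
            dict(n_subjects=5),
            dict(noise_sd=0.0),
            dict(latent_correlation=1.0),
            dict(sex_ratio=1.5),
            dict(effect_total={"nonexistent": 1.0}),
        ],
    )
    def test_invalid_spec_rejected(self, bad):
        with pytest.raises(CohortError):
            efs.GeneratorSpec(**bad)


class TestOutcomes:
    def test_five_percent_flagged_in_one_group(self, rng):
        t = pd.DataFrame(
            {
                "subject_id": np.arange(100),
                "sex": 0,
                "age": 10.2,
                "waist": rng.permutation(np.linspace(50, 90, 100)),
                "bmi": rng.permutation(np.linspace(12, 30, 100)),
            }
        )
        out = efs.derive_outcomes(t)
        assert out["obw"].sum() == 5
        assert out["obwho"].sum() == 5
        # the flagged five are the five largest waists
        assert set(out.loc[out["obw"] == 1, "waist"]) == set(np.sort(t["waist"])[-5:])

    def test_all_ties_all_flagged(self):
        t = pd.DataFrame(
            {
                "subject_id": np.arange(30),
                "sex": 1,
                "age": 10.0,
                "waist": 66.0,
                "bmi": 18.0,
            }
        )
        out = efs.derive_outcomes(t)
        assert out["obw"].all() and out["obwho"].all()

    def test_groups_match_bruteforce(self, rng):
        n = 240
        t = pd.DataFrame(
            {
                "subject_id": np.arange(n),
                "sex": rng.integers(0, 2, n),
                "age": rng.normal(10, 0.6, n),
                "waist": rng.normal(65, 6, n),
                "bmi": rng.normal(17.5, 2.5, n),
            }
        )
        out = efs.derive_outcomes(t)
        for (s, a), grp in out.groupby([out["sex"], np.floor(out["age"]).astype(int)]):
            cut = np.quantile(grp["waist"], 0.95)
            expect = (grp["waist"] >= cut).astype(int)
            assert (grp["obw"] == expect).all()

    def test_missing_column_rejected(self):
        with pytest.raises(CohortError, match="waist"):
            efs.derive_outcomes(pd.DataFrame({"bmi": [1.0], "age": [10], "sex": [0]}))


class TestPreprocess:
    def test_standardization_and_idempotence(self, default_cohort):
        for m in BIOMARKERS:
            assert abs(default_cohort[m].mean()) < 1e-8
            assert abs(default_cohort[m].var(ddof=0) - 1.0) < 1e-8
        again = efs.preprocess(default_cohort)
        for m in BIOMARKERS:
            np.testing.assert_allclose(again[m], default_cohort[m], atol=1e-12)

    def test_fitness_binarization_strict_median_rule(self):
        t = efs.generate_cohort(efs.GeneratorSpec(seed=3)).iloc[:4].copy()
        t["fitness_raw"] = [1.0, 2.0, 3.0, 4.0]
        out = efs.preprocess(t)
        assert out["fitness"].tolist() == [0, 0, 1, 1]

    def test_external_median(self):
        t = efs.generate_cohort(efs.GeneratorSpec(seed=3)).iloc[:4].copy()
        t["fitness_raw"] = [1.0, 2.0, 3.0, 4.0]
        out = efs.preprocess(t, fitness_median=3.5)
        assert out["fitness"].tolist() == [0, 0, 0, 1]

    def test_zero_variance_column_named(self):
        t = efs.generate_cohort(efs.GeneratorSpec(seed=3))
        t["il_6"] = 1.23
        with pytest.raises(CohortError, match="il_6"):
            efs.preprocess(t)


class TestInfluenceExclusion:
    def test_clean_cohort_keeps_everyone(self, default_cohort):
        kept, excluded = efs.exclude_influential(default_cohort, "obw")
        assert excluded == []
        assert len(kept) == len(default_cohort)

    def test_planted_extreme_value_excluded(self, default_cohort):
        t = default_cohort.copy()
        t.loc[10, "mpo"] = 50.0
        kept, excluded = efs.exclude_influential(t, "obw")
        assert t.loc[10, "subject_id"] in excluded

    def test_partition_property(self, default_cohort):
        t = default_cohort.copy()
        t.loc[3, "il_8"] = 60.0
        kept, excluded = efs.exclude_influential(t, "obw")
        assert len(kept) + len(excluded) == len(t)
        assert not set(kept["subject_id"]) & set(excluded)

    def test_cooks_option_runs(self, default_cohort):
        kept, excluded = efs.exclude_influential(
            default_cohort, "obw", statistic="cooks", threshold=1.0
        )
        assert len(kept) + len(excluded) == len(default_cohort)


def test_cohort_csv_roundtrip(tmp_path, default_cohort):
    path = tmp_path / "cohort.csv"
    spec = efs.GeneratorSpec(seed=11)
    efs.write_cohort(default_cohort, path, spec)
    back = efs.read_cohort(path)
    pd.testing.assert_frame_equal(back, default_cohort, check_exact=False, atol=1e-12)
    spec2 = efs.GeneratorSpec.from_json(str(path) + ".spec.json")
    assert spec2 == spec
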
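"""Exposure processing: LOD substitution, classification, screening."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pfasmeth.exposures import (ExposureTable, classify_analyte,
                                correlate_exposures, classify_all,
                                impute_missing_covariates, screen_confounders,
                                substitute_below_lod)

# detection profile of the published nine-analyte panel: fraction of samples
# below the LOD per analyte.  Four analytes >89% detected, PFDA well
# detected (just under 40% below the LOD, hence continuous), two moderately
# detected, two poorly detected.
NINE_ANALYTE_PROFILE = {
    "PFHxS": 0.02, "PFOS": 0.02, "PFOA": 0.05, "PFNA": 0.11, "PFDA": 0.399,
    "PFUnDA": 0.645, "MeFOSAA": 0.624, "PFOSA": 0.85, "PFHpA": 0.90,
}


class TestSubstitution:
    def test_flagged_value_becomes_lod_over_sqrt2(self):
        subjects = ["a", "b"]
        vals = pd.DataFrame({"X": [np.nan, 0.5]}, index=subjects)
        flags = pd.DataFrame({"X": [True, False]}, index=subjects)
        table = ExposureTable(vals, flags, pd.Series({"X": 0.1}))
        out = substitute_below_lod(table)
        assert out.values.loc["a", "X"] == pytest.approx(0.1 / np.sqrt(2))
        assert out.values.loc["b", "X"] == 0.5

    def test_no_flags_is_identity(self, toy_exposure_table):
        t = toy_exposure_table
        t2 = ExposureTable(t.values.fillna(1.0),
                           t.below_lod & False, t.lod)
        out = substitute_below_lod(t2)
        pd.testing.assert_frame_equal(out.values, t2.values)

    def test_substitution_preserves_detected_order(self, toy_exposure_table):
        out = substitute_below_lod(toy_exposure_table)
        detected = ~toy_exposure_table.below_lod["A"]
        orig = toy_exposure_table.values.loc[detected, "A"]
        new = out.values.loc[detected, "A"]
        assert (orig.rank() == new.rank()).all()

    def test_missing_lod_errors(self):
        vals = pd.DataFrame({"X": [1.0]}, index=["a"])
        flags = pd.DataFrame({"X": [False]}, index=["a"])
        with pytest.raises(ValueError, match="LOD"):
            ExposureTable(vals, flags, pd.Series(dtype=float))


class TestClassification:
    @pytest.mark.parametrize("frac,expected", [
        (0.645, "categorical"),   # moderately detected analyte
        (0.624, "categorical"),
        (0.11, "continuous"),     # well detected
        (0.02, "continuous"),
        (0.85, "excluded"),       # poorly detected
        (0.40, "categorical"),    # boundary fractions go to the middle class
        (0.80, "categorical"),
        (0.399, "continuous"),
        (0.801, "excluded"),
    ])
    def test_rule_table(self, frac, expected):
        assert classify_analyte(frac).analyte_class == expected

    def test_nine_analyte_profile_splits_5_2_2(self):
        """The printed detection profile yields 5 continuous, 2 categorical,
        2 excluded analytes."""
        classes = [classify_analyte(f, analyte=a).analyte_class
                   for a, f in NINE_ANALYTE_PROFILE.items()]
        counts = pd.Series(classes).value_counts()
        assert counts["continuous"] == 5
        assert counts["categorical"] == 2
        assert counts["excluded"] == 2

    @given(st.floats(min_value=0, max_value=1))
    @settings(max_examples=200, deadline=None)
    def test_step_function_of_fraction(self, f):
        cls = classify_analyte(f).analyte_class
        if f > 0.80:
            assert cls == "excluded"
        elif f >= 0.40:
            assert cls == "categorical"
        else:
            assert cls == "continuous"

    def test_out_of_range_fraction_errors(self):
        with pytest.raises(ValueError):
            classify_analyte(1.2)


class TestCorrelation:
    def test_unit_diagonal(self, toy_exposure_table):
        classes = classify_all(toy_exposure_table)
        r, p = correlate_exposures(toy_exposure_table, classes)
        assert np.allclose(np.diag(r), 1.0)
        assert (r.values == r.values.T).all()

    def test_planted_log_scale_correlation_recovered(self):
        rng = np.random.default_rng(0)
        n = 200
        z1 = rng.normal(size=n)
        z2 = 0.7 * z1 + np.sqrt(1 - 0.49) * rng.normal(size=n)
        vals = pd.DataFrame({"A": np.exp(1 + 0.5 * z1),
                             "B": np.exp(1 + 0.5 * z2)})
        flags = pd.DataFrame(False, index=vals.index, columns=["A", "B"])
        t = ExposureTable(vals, flags, pd.Series({"A": .1, "B": .1}))
        r, _ = correlate_exposures(t, classify_all(t))
        assert abs(r.loc["A", "B"] - 0.7) < 0.1

    def test_independent_analytes_near_zero(self):
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(20):
            vals = pd.DataFrame({"A": rng.lognormal(1, .5, 500),
                                 "B": rng.lognormal(1, .5, 500)})
            flags = pd.DataFrame(False, index=vals.index, columns=["A", "B"])
            t = ExposureTable(vals, flags, pd.Series({"A": .1, "B": .1}))
            r, p = correlate_exposures(t, classify_all(t))
            if abs(r.loc["A", "B"]) < 0.1 and p.loc["A", "B"] > 0.05:
                hits += 1
        assert hits >= 18


class TestConfounderScreen:
    def test_planted_association_selected(self):
        rng = np.random.default_rng(2)
        n = 300
        lnx = rng.normal(1.5, 0.5, n)
        expo = pd.DataFrame({"PFOS": lnx})
        cov = pd.DataFrame({"noisy_copy": lnx + rng.normal(0, 0.3, n),
                            "independent": rng.normal(size=n)})
        rep = screen_confounders(expo, cov)
        sel = rep.set_index(["covariate", "analyte"])["selected"]
        assert sel.loc[("noisy_copy", "PFOS")]

    def test_null_selection_rate_near_alpha(self):
        rng = np.random.default_rng(3)
        n = 500
        picks = []
        for _ in range(200):
            expo = pd.DataFrame({"A": rng.normal(size=n)})
            cov = pd.DataFrame({"c": rng.normal(size=n)})
            rep = screen_confounders(expo, cov)
            picks.append(bool(rep["selected"].iloc[0]))
        rate = np.mean(picks)
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 200)

    def test_constant_covariate_excluded(self):
        expo = pd.DataFrame({"A": [1.0, 2.0, 3.0]})
        cov = pd.DataFrame({"c": [1.0, 1.0, 1.0]})
        rep = screen_confounders(expo, cov)
        assert (rep["test"] == "constant").all()


class TestImputation:
    def test_no_missing_is_identity(self):
        df = pd.DataFrame({"x": [0.0, 1.0, 1.0]})
        out = impute_missing_covariates(df, seed=0)
        pd.testing.assert_frame_equal(out, df)

    def test_same_seed_same_completion(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"x": rng.binomial(1, 0.7, 50).astype(float)})
        df.loc[:9, "x"] = np.nan
        a = impute_missing_covariates(df, seed=42)
        b = impute_missing_covariates(df, seed=42)
        pd.testing.assert_frame_equal(a, b)
        assert a["x"].notna().all()

    def test_imputed_frequency_matches_complete_cases(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({"x": rng.binomial(1, 0.7, 200).astype(float)})
        miss = rng.choice(200, 40, replace=False)
        df.loc[miss, "x"] = np.nan
        p_complete = df["x"].dropna().mean()
        draws = [impute_missing_covariates(df, seed=s).loc[miss, "x"].mean()
                 for s in range(300)]
        assert abs(np.mean(draws) - p_complete) < 0.03

    def test_fully_missing_errors(self):
        df = pd.DataFrame({"x": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="entirely missing"):
            impute_missing_covariates(df, seed=0)
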
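"""Outcome models, mediation screen, kernel machine variance-component test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pfasmeth.mediation import (MediationCandidateSet,
                                gene_wise_and_global_mediation, kernel_matrix,
                                km_mediation_test, outcome_exposure_models,
                                screen_mediators, site_outcome_pvalues)

# published exposure-outcome regression summary used as the tier-2 worked
# example: (exposure, outcome) -> p-value of the exposure coefficient
OUTCOME_MODEL_PVALUES = [
    ("PFHxS", "gestational_age", 0.85), ("PFHxS", "fenton_z", 0.036),
    ("PFOS", "gestational_age", 0.40), ("PFOS", "fenton_z", 0.41),
    ("PFOA", "gestational_age", 0.75), ("PFOA", "fenton_z", 0.79),
    ("PFNA", "gestational_age", 0.089), ("PFNA", "fenton_z", 0.91),
    ("PFDA", "gestational_age", 0.114), ("PFDA", "fenton_z", 0.383),
    ("PFUnDA", "gestational_age", 0.019), ("PFUnDA", "fenton_z", 0.95),
    ("MeFOSAA", "gestational_age", 0.45), ("MeFOSAA", "fenton_z", 0.71),
]


def _cov(n, rng):
    return pd.DataFrame({
        "parity": rng.poisson(1, n).astype(float),
        "race": rng.binomial(1, 0.07, n).astype(float),
        "smoking": rng.binomial(1, 0.1, n).astype(float),
    })


class TestOutcomeModels:
    def test_planted_slope_recovered(self):
        rng = np.random.default_rng(0)
        n = 141
        ests = []
        for _ in range(100):
            cov = _cov(n, rng)
            e = rng.normal(size=n)
            y = 39.5 - 0.46 * e + 0.1 * cov["parity"] + rng.normal(0, 1.2, n)
            tab = outcome_exposure_models(
                pd.DataFrame({"ga": y}), pd.DataFrame({"E": e}), cov)
            ests.append(tab["coef"].iloc[0])
        assert abs(np.mean(ests) + 0.46) < 0.05

    def test_null_screen_rate_near_ten_percent(self):
        rng = np.random.default_rng(1)
        n = 141
        hits = 0
        reps = 300
        for _ in range(reps):
            cov = _cov(n, rng)
            e = rng.normal(size=n)
            y = rng.normal(size=n)
            tab = outcome_exposure_models(
                pd.DataFrame({"y": y}), pd.DataFrame({"E": e}), cov)
            hits += tab["p_value"].iloc[0] < 0.1
        assert abs(hits / reps - 0.10) < 3 * np.sqrt(0.1 * 0.9 / reps)

    def test_zero_variance_exposure_errors(self):
        rng = np.random.default_rng(2)
        cov = _cov(50, rng)
        with pytest.raises(ValueError, match="zero variance"):
            outcome_exposure_models(pd.DataFrame({"y": rng.normal(size=50)}),
                                    pd.DataFrame({"E": np.ones(50)}), cov)


class TestScreen:
    def test_printed_tier2_pass_set_is_three_exposures(self):
        """Applying the p < 0.1 tier-2 screen to the published outcome-model
        p-values carries forward exactly PFHxS->Fenton z, PFNA->GA,
        PFUnDA->GA."""
        tab = pd.DataFrame(OUTCOME_MODEL_PVALUES,
                           columns=["exposure", "outcome", "p_value"])
        passing = tab[tab["p_value"] < 0.1]
        assert set(zip(passing["exposure"], passing["outcome"])) == {
            ("PFHxS", "fenton_z"), ("PFNA", "gestational_age"),
            ("PFUnDA", "gestational_age")}

    def test_zero_thresholds_give_no_candidates(self):
        tab = pd.DataFrame(OUTCOME_MODEL_PVALUES,
                           columns=["exposure", "outcome", "p_value"])
        out = screen_mediators({}, tab, {}, thresholds=(1e-12, 1e-12, 1e-12))
        assert out == []

    def test_three_tier_screen_assembles_candidates(self):
        sites = [f"cg{i}" for i in range(10)]
        ewas = {("PFNA", "5hmC"): pd.DataFrame(
            {"q_value": [0.01] * 4 + [0.5] * 6}, index=sites)}
        outcome = pd.DataFrame([("PFNA", "gestational_age", 0.05)],
                               columns=["exposure", "outcome", "p_value"])
        p3 = {("PFNA", "gestational_age", "5hmC"): pd.Series(
            [0.01, 0.2, 0.03, 0.9] + [0.01] * 6, index=sites)}
        cands = screen_mediators(ewas, outcome, p3)
        assert len(cands) == 1
        assert cands[0].sites == ["cg0", "cg2"]


class TestKernel:
    def test_identical_subjects_give_all_ones(self):
        M = np.tile([[0.2, 0.5]], (6, 1))
        K = kernel_matrix(M, bandwidth=1.0)
        np.testing.assert_allclose(K, 1.0)

    def test_linear_kernel_is_centered_gram(self):
        rng = np.random.default_rng(3)
        M = rng.normal(size=(10, 4))
        K = kernel_matrix(M, kernel="linear")
        Mc = M - M.mean(axis=0)
        np.testing.assert_allclose(K, Mc @ Mc.T)

    def test_gaussian_kernel_psd(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            K = kernel_matrix(rng.normal(size=(30, 6)))
            assert np.linalg.eigvalsh(K).min() >= -1e-10

    def test_invariance_to_column_order_and_scale(self):
        rng = np.random.default_rng(5)
        Y = rng.normal(size=50)
        E = rng.normal(size=50)
        X = rng.normal(size=(50, 2))
        M = rng.uniform(0.1, 0.9, size=(50, 5))
        p1 = km_mediation_test(Y, E, X, M).p_value
        p2 = km_mediation_test(Y, E, X, M[:, ::-1]).p_value
        p3 = km_mediation_test(Y, E, X, M * 3.0 + 1.0).p_value
        assert p1 == pytest.approx(p2, rel=1e-10)
        assert p1 == pytest.approx(p3, rel=1e-10)

    def test_zero_bandwidth_errors(self):
        with pytest.raises(ValueError):
            kernel_matrix(np.random.default_rng(6).normal(size=(5, 2)),
                          bandwidth=0.0)


class TestScoreTest:
    def test_linear_kernel_single_mediator_matches_f_test(self):
        """With a linear kernel and one mediator the variance-component
        score test tracks the OLS F-test of that mediator."""
        rng = np.random.default_rng(7)
        rel = []
        for _ in range(30):
            n = 141
            X = rng.normal(size=(n, 2))
            E = rng.normal(size=n)
            m = rng.normal(size=n)
            Y = 0.25 * m + rng.normal(size=n)
            res = km_mediation_test(Y, E, X, m[:, None], kernel="linear")
            # OLS F-test of m given [1, X, E]
            W = np.column_stack([np.ones(n), X, E])
            Wm = np.column_stack([W, m])
            rss0 = Y @ Y - Y @ W @ np.linalg.lstsq(W, Y, rcond=None)[0]
            rss1 = Y @ Y - Y @ Wm @ np.linalg.lstsq(Wm, Y, rcond=None)[0]
            F = (rss0 - rss1) / (rss1 / (n - Wm.shape[1]))
            p_f = stats.f.sf(F, 1, n - Wm.shape[1])
            if p_f > 1e-6:
                rel.append(abs(res.p_value - p_f) / p_f)
        assert np.median(rel) < 0.10

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(8)
        rej = 0
        reps = 400
        for _ in range(reps):
            n = 141
            X = rng.normal(size=(n, 3))
            E = rng.normal(size=n)
            M = rng.uniform(0, 1, size=(n, 10))
            Y = 0.3 * E + rng.normal(size=n)
            res = km_mediation_test(Y, E, X, M)
            rej += res.p_value < 0.05
        assert 0.02 <= rej / reps <= 0.08

    def test_strong_mediation_detected(self):
        rng = np.random.default_rng(9)
        power = 0
        reps = 60
        for _ in range(reps):
            n = 141
            X = rng.normal(size=(n, 2))
            E = rng.normal(size=n)
            M = 0.5 * E[:, None] + rng.normal(size=(n, 5))
            signal = M @ rng.normal(size=5) * 0.4
            Y = signal + rng.normal(size=n)
            res = km_mediation_test(Y, E, X, M)
            power += res.p_value < 0.05
        assert power / reps >= 0.8

    def test_singular_design_errors(self):
        rng = np.random.default_rng(10)
        n = 50
        X = np.ones((n, 2))
        with pytest.raises(ValueError, match="singular"):
            km_mediation_test(rng.normal(size=n), rng.normal(size=n), X,
                              rng.normal(size=(n, 2)))


class TestGeneWise:
    def _setup(self, seed=11):
        rng = np.random.default_rng(seed)
        n = 60
        subjects = [f"S{i}" for i in range(n)]
        sites = [f"cg{i}" for i in range(8)]
        meth = pd.DataFrame(rng.uniform(0.1, 0.9, (8, n)), index=sites,
                            columns=subjects)
        cov = _cov(n, rng)
        cov.index = subjects
        outcomes = pd.DataFrame({"ga": rng.normal(39, 1, n)}, index=subjects)
        evars = pd.DataFrame({"PFNA": rng.normal(size=n)}, index=subjects)
        return meth, cov, outcomes, evars, sites

    def test_single_gene_equals_global(self):
        meth, cov, outcomes, evars, sites = self._setup()
        cand = MediationCandidateSet("PFNA", "ga", "5hmC", sites,
                                     genes={s: "GENE1" for s in sites})
        tab = gene_wise_and_global_mediation(
            [cand], outcomes, evars, cov, {"5hmC": meth})
        by_group = tab.set_index("group")
        assert by_group.loc["GENE1", "p_value"] == pytest.approx(
            by_group.loc["all", "p_value"])

    def test_bh_family_is_within_exposure(self):
        meth, cov, outcomes, evars, sites = self._setup()
        genes = {s: f"G{i % 3}" for i, s in enumerate(sites)}
        cand = MediationCandidateSet("PFNA", "ga", "5hmC", sites, genes=genes)
        tab = gene_wise_and_global_mediation(
            [cand], outcomes, evars, cov, {"5hmC": meth})
        from pfasmeth.ewas import bh_adjust

        np.testing.assert_allclose(
            np.sort(tab["q_value"]),
            np.sort(bh_adjust(tab["p_value"].to_numpy())))


class TestSiteOutcome:
    def test_associated_site_gets_small_p(self):
        rng = np.random.default_rng(12)
        n = 100
        subjects = [f"S{i}" for i in range(n)]
        cov = _cov(n, rng)
        cov.index = subjects
        m = rng.uniform(0.2, 0.8, n)
        y = pd.Series(5 * m + rng.normal(0, 0.5, n), index=subjects)
        meth = pd.DataFrame({s: v for s, v in zip(subjects, m)},
                            index=["cgA"])
        null_site = pd.DataFrame(
            rng.uniform(0.2, 0.8, (1, n)), index=["cgB"], columns=subjects)
        p = site_outcome_pvalues(y, pd.concat([meth, null_site]), cov)
        assert p["cgA"] < 1e-6
        assert p["cgB"] > 0.001
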
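"""Synthetic cohort generator: reproducibility, censoring, truth invariants."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pfasmeth.synthetic import (AnalyteSpec, CohortConfig, EffectMap,
                                MediationSpec, default_analytes,
                                generate_cohort, generate_reference_panel,
                                mix_reference_samples)


class TestReproducibility:
    def test_same_seed_bit_identical(self):
        a = generate_cohort(CohortConfig(n_subjects=20, n_paired=10,
                                         n_sites=50, seed=7))
        b = generate_cohort(CohortConfig(n_subjects=20, n_paired=10,
                                         n_sites=50, seed=7))
        pd.testing.assert_frame_equal(a.exposures.values, b.exposures.values)
        pd.testing.assert_frame_equal(a.bs.betas, b.bs.betas)
        pd.testing.assert_frame_equal(a.outcomes, b.outcomes)
        pd.testing.assert_frame_equal(a.truth.true_hmc, b.truth.true_hmc)

    def test_different_seed_differs(self):
        a = generate_cohort(CohortConfig(n_subjects=20, n_paired=10,
                                         n_sites=50, seed=7))
        b = generate_cohort(CohortConfig(n_subjects=20, n_paired=10,
                                         n_sites=50, seed=8))
        assert not a.bs.betas.equals(b.bs.betas)


class TestExposures:
    def test_high_lod_censors_expected_fraction(self):
        """With the LOD placed at the 80th percentile of an analyte's
        log-normal distribution, ~80% of draws fall below it."""
        q80 = float(np.exp(1.0 + 0.5 * stats.norm.ppf(0.8)))
        spec = AnalyteSpec("X", log_mean=1.0, log_sd=0.5, lod=q80)
        cfg = CohortConfig(n_subjects=500, n_paired=10, n_sites=10,
                           analytes=[spec], exposure_correlation=0.0, seed=1)
        cohort = generate_cohort(cfg)
        frac = cohort.exposures.below_lod["X"].mean()
        se = np.sqrt(0.8 * 0.2 / 500)
        assert abs(frac - 0.8) < 3 * se

    def test_geometric_moments_converge(self):
        cfg = CohortConfig(n_subjects=2000, n_paired=10, n_sites=10, seed=2)
        cohort = generate_cohort(cfg)
        ln = np.log(cohort.truth.uncensored_exposures)
        for a in default_analytes():
            mean_se = a.log_sd / np.sqrt(2000)
            assert abs(ln[a.name].mean() - a.log_mean) < 3 * mean_se
            sd_se = a.log_sd / np.sqrt(2 * 1999)
            assert abs(ln[a.name].std() - a.log_sd) < 3 * sd_se

    def test_censored_values_masked_but_truth_kept(self):
        cohort = generate_cohort(CohortConfig(n_subjects=200, n_paired=10,
                                              n_sites=10, seed=3))
        flagged = cohort.exposures.below_lod["PFOSA"]
        assert flagged.mean() > 0.5
        assert cohort.exposures.values.loc[flagged, "PFOSA"].isna().all()
        assert cohort.truth.uncensored_exposures["PFOSA"].notna().all()

    def test_non_psd_correlation_rejected(self):
        R = np.array([[1.0, 0.99, -0.99], [0.99, 1.0, 0.99],
                      [-0.99, 0.99, 1.0]])
        cfg = CohortConfig(analytes=default_analytes()[:3],
                           exposure_correlation=R)
        with pytest.raises(ValueError, match="PSD"):
            generate_cohort(cfg)

    def test_mediator_site_out_of_range_rejected(self):
        cfg = CohortConfig(n_sites=10, mediation=MediationSpec(
            mediator_sites=(50,), alpha=(1.0,), theta=(1.0,)))
        with pytest.raises(ValueError, match="out of range"):
            generate_cohort(cfg)


class TestMethylation:
    def test_truth_on_simplex(self, small_cohort):
        t = small_cohort.truth
        total = t.true_mc.to_numpy() + t.true_hmc.to_numpy()
        assert (t.true_mc.to_numpy() >= 0).all()
        assert (t.true_hmc.to_numpy() >= 0).all()
        assert (total <= 1.0 + 1e-12).all()

    def test_cell_proportions_sum_to_one(self, small_cohort):
        np.testing.assert_allclose(
            small_cohort.truth.true_cell_props.sum(axis=1), 1.0)

    def test_bs_exceeds_oxbs_in_expectation(self, small_cohort):
        paired = small_cohort.oxbs.samples
        diff = (small_cohort.bs.betas[paired]
                - small_cohort.oxbs.betas[paired]).to_numpy()
        # per-site mean difference equals true 5-hmC plus noise; on average
        # it must be positive
        assert diff.mean() > 0
        assert (diff.mean(axis=1) > -0.02).all()

    def test_infinite_precision_gives_exact_hmc(self):
        cfg = CohortConfig(n_subjects=10, n_paired=10, n_sites=30,
                           assay_precision=np.inf, seed=4)
        cohort = generate_cohort(cfg)
        diff = cohort.bs.betas - cohort.oxbs.betas
        np.testing.assert_allclose(diff.to_numpy(),
                                   cohort.truth.true_hmc.to_numpy(),
                                   atol=2e-6)

    def test_planted_effect_changes_methylation(self):
        base = CohortConfig(n_subjects=100, n_paired=10, n_sites=20, seed=5)
        null = generate_cohort(base)
        em = EffectMap(exposure="PFOS", total={0: 1.5})
        alt = generate_cohort(CohortConfig(n_subjects=100, n_paired=10,
                                           n_sites=20, effect_map=em, seed=5))
        site = alt.bs.betas.index[0]
        lnE = np.log(alt.truth.uncensored_exposures["PFOS"])
        r_alt = np.corrcoef(alt.truth.true_mc.loc[site], lnE)[0, 1]
        r_null = np.corrcoef(null.truth.true_mc.loc[site], lnE)[0, 1]
        assert r_alt > 0.5 > abs(r_null)


class TestReferencePanel:
    def test_shape_bounds_and_signature_contrast(self):
        panel = generate_reference_panel(CohortConfig(seed=0))
        assert panel.shape == (350, 7)
        assert ((panel >= 0) & (panel <= 1)).all().all()
        rng_by_site = panel.max(axis=1) - panel.min(axis=1)
        assert (rng_by_site >= 0.5).all()

    def test_mixing_is_linear_when_noiseless(self):
        panel = generate_reference_panel(CohortConfig(seed=1))
        w = np.array([[0.3, 0.2, 0.1, 0.1, 0.1, 0.1, 0.1]])
        s = mix_reference_samples(panel, w, precision=np.inf)
        np.testing.assert_allclose(s["mix0"], panel.to_numpy() @ w[0])

    def test_too_few_types_errors(self):
        from pfasmeth.synthetic import CellReferenceSpec

        cfg = CohortConfig(cell_reference=CellReferenceSpec(cell_types=("A",)))
        with pytest.raises(ValueError, match="2 cell types"):
            generate_reference_panel(cfg)


class TestRoundTrip:
    def test_write_and_reload_config(self, tmp_path):
        cfg = CohortConfig(n_subjects=12, n_paired=6, n_sites=20, seed=9,
                           effect_map=EffectMap(exposure="PFOS",
                                                total={1: 0.5}))
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        cfg2 = CohortConfig.from_yaml(path)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg2)
        pd.testing.assert_frame_equal(a.bs.betas, b.bs.betas)

    def test_cohort_tables_written(self, tmp_path):
        cohort = generate_cohort(CohortConfig(n_subjects=8, n_paired=4,
                                              n_sites=10, seed=10))
        cohort.write(tmp_path / "out")
        reloaded = pd.read_csv(tmp_path / "out" / "betas_bs.tsv", sep="\t",
                               index_col=0)
        pd.testing.assert_frame_equal(reloaded, cohort.bs.betas,
                                      check_names=False)
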
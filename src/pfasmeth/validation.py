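"""Validation studies: worked examples and simulation-based checks.

Bundles the package's self-validation suite so the same computations back
both the test suite and the reproduction script: rule-based worked examples
(exposure classification, mediation tier-2 screen, long-matrix layout), a
brute-force likelihood oracle for the MLML decomposition, and seeded
simulation studies measuring EWAS calibration (genomic inflation, FDR
control), planted-effect recovery, type-interaction estimator behavior,
kernel-mediation calibration and power, and the BH/deconvolution oracles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from .arrayqc import clamp_proportions, deconvolve_cell_types
from .betamixed import fit_beta_mixed
from .ewas import ModelSpec, bh_adjust, genomic_inflation, run_ewas
from .exposures import (analysis_variables, classify_all, classify_analyte,
                        impute_missing_covariates)
from .mediation import km_mediation_test
from .mlml import build_long_matrix, estimate_proportions
from .synthetic import (CohortConfig, EffectMap, generate_cohort,
                        generate_reference_panel, mix_reference_samples)

# ---------------------------------------------------------------------------
# printed inputs for the worked examples
# ---------------------------------------------------------------------------

# fraction of samples below the LOD for the nine-analyte first-trimester
# panel.  Four analytes >89% detected; PFDA well detected (just under the
# 40% boundary, hence continuous); two moderately detected; two poorly
# detected.
NINE_ANALYTE_DETECTION = {
    "PFHxS": 0.02, "PFOS": 0.02, "PFOA": 0.05, "PFNA": 0.11, "PFDA": 0.399,
    "PFUnDA": 0.645, "MeFOSAA": 0.624, "PFOSA": 0.85, "PFHpA": 0.90,
}

# exposure-outcome regression summary (coefficient, p-value of the exposure
# term) feeding the tier-2 mediation screen worked example
OUTCOME_MODEL_SUMMARY = [
    ("PFHxS", "gestational_age", 0.04, 0.85),
    ("PFHxS", "fenton_z", -0.25, 0.036),
    ("PFOS", "gestational_age", -0.160, 0.40),
    ("PFOS", "fenton_z", -0.12, 0.41),
    ("PFOA", "gestational_age", -0.056, 0.75),
    ("PFOA", "fenton_z", -0.036, 0.79),
    ("PFNA", "gestational_age", -0.31, 0.089),
    ("PFNA", "fenton_z", -0.016, 0.91),
    ("PFDA", "gestational_age", -0.27, 0.114),
    ("PFDA", "fenton_z", 0.13, 0.383),
    ("PFUnDA", "gestational_age", -0.46, 0.019),
    ("PFUnDA", "fenton_z", 0.010, 0.95),
    ("MeFOSAA", "gestational_age", 0.15, 0.45),
    ("MeFOSAA", "fenton_z", -0.059, 0.71),
]


def classification_worked_example() -> dict:
    """Class counts from the printed nine-analyte detection profile."""
    classes = [classify_analyte(f, analyte=a).analyte_class
               for a, f in NINE_ANALYTE_DETECTION.items()]
    s = pd.Series(classes).value_counts()
    return {"continuous": int(s.get("continuous", 0)),
            "categorical": int(s.get("categorical", 0)),
            "excluded": int(s.get("excluded", 0))}


def tier2_screen_worked_example(threshold: float = 0.1) -> list:
    """Exposure-outcome pairs carried into mediation by the p < 0.1 screen."""
    tab = pd.DataFrame(OUTCOME_MODEL_SUMMARY,
                       columns=["exposure", "outcome", "coef", "p_value"])
    keep = tab[tab["p_value"] < threshold]
    return sorted(zip(keep["exposure"], keep["outcome"]))


def long_matrix_rows_per_site(n_subjects: int = 70, seed: int = 0) -> int:
    """Rows per site in the type-labeled long matrix for paired subjects."""
    rng = np.random.default_rng(seed)
    subj = [f"S{i}" for i in range(n_subjects)]
    mc = pd.DataFrame(rng.uniform(0.2, 0.6, (3, n_subjects)),
                      index=["cg0", "cg1", "cg2"], columns=subj)
    hmc = pd.DataFrame(rng.uniform(0.0, 0.2, (3, n_subjects)),
                       index=mc.index, columns=subj)
    long = build_long_matrix(mc, hmc)
    counts = long.groupby("site").size()
    assert counts.nunique() == 1
    return int(counts.iloc[0])


# ---------------------------------------------------------------------------
# MLML grid-search oracle
# ---------------------------------------------------------------------------

def mlml_grid_agreement(n_grid: int = 101, step: float = 1e-4,
                        n_bs: float = 100.0, n_oxbs: float = 100.0) -> dict:
    """Compare the closed-form estimator with a dense ML grid search.

    The joint binomial log-likelihood factorizes as f(bs; s) + g(oxbs; p_m)
    with s = p_m + p_h >= p_m; for fixed p_m the first factor is concave in
    s with unconstrained optimum at s = bs, so the constrained optimum is
    s = max(bs, p_m).  That reduces the oracle to a dense 1-D grid over
    p_m, evaluated for every point of an n_grid x n_grid (bs, oxbs)
    lattice.  Returns the maximum absolute deviation in (p_m, p_h) and the
    worst-case deviation on the bs < oxbs (boundary) half.
    """
    g = np.linspace(0, 1, n_grid)
    bs, ox = np.meshgrid(g, g)
    bs, ox = bs.ravel(), ox.ravel()
    d = estimate_proportions(bs, ox, n_bs=n_bs, n_oxbs=n_oxbs)

    pm_grid = np.clip(np.arange(0.0, 1.0 + step / 2, step), 1e-12, 1 - 1e-12)
    max_dev = 0.0
    max_dev_boundary = 0.0
    chunk = 500
    for lo in range(0, bs.size, chunk):
        hi = min(lo + chunk, bs.size)
        b = bs[lo:hi, None]
        o = ox[lo:hi, None]
        s = np.clip(np.maximum(b, pm_grid[None, :]), 1e-12, 1 - 1e-12)
        ll = (n_bs * (b * np.log(s) + (1 - b) * np.log1p(-s))
              + n_oxbs * (o * np.log(pm_grid[None, :])
                          + (1 - o) * np.log1p(-pm_grid[None, :])))
        j = np.argmax(ll, axis=1)
        pm_o = pm_grid[j]
        ph_o = np.maximum(np.take_along_axis(s, j[:, None], 1)[:, 0] - pm_o, 0)
        dev = np.maximum(np.abs(d.p_m[lo:hi] - pm_o),
                         np.abs(d.p_h[lo:hi] - ph_o))
        max_dev = max(max_dev, float(dev.max()))
        mask = bs[lo:hi] < ox[lo:hi]
        if mask.any():
            max_dev_boundary = max(max_dev_boundary, float(dev[mask].max()))
    boundary_ok = bool((d.p_h[d.boundary] == 0).all())
    return {"max_abs_dev": max_dev, "max_abs_dev_boundary": max_dev_boundary,
            "negative_inputs_give_zero_hmc": boundary_ok}


# ---------------------------------------------------------------------------
# EWAS simulation studies
# ---------------------------------------------------------------------------

def _cohort_ewas(seed, effect_map=None, n_subjects=141, n_sites=2000,
                 exposure="PFOS"):
    cfg = CohortConfig(n_subjects=n_subjects, n_paired=min(70, n_subjects),
                       n_sites=n_sites, effect_map=effect_map or EffectMap(),
                       seed=seed)
    cohort = generate_cohort(cfg)
    classes = classify_all(cohort.exposures)
    evars = analysis_variables(cohort.exposures, classes)
    cov = impute_missing_covariates(cohort.covariates, seed=seed + 1,
                                    columns=["smoking", "race"])
    bs = clamp_proportions(cohort.bs)
    tab = run_ewas(bs.betas, evars[exposure], cov,
                   ModelSpec(exposure=exposure))
    return cohort, tab


def ewas_null_study(n_runs: int = 20, seed: int = 0) -> dict:
    """Global-null cohorts: genomic inflation and q < 0.05 hit counts."""
    lams, hits = [], []
    for k in range(n_runs):
        _, tab = _cohort_ewas(seed * 1000 + k)
        lams.append(genomic_inflation(tab["p_value"].dropna().to_numpy()))
        hits.append(int((tab["q_value"] < 0.05).sum()))
    return {"lambdas": lams, "mean_lambda": float(np.mean(lams)),
            "hits": hits,
            "zero_hit_fraction": float(np.mean([h == 0 for h in hits]))}


def ewas_recovery_study(n_runs: int = 20, seed: int = 0,
                        n_planted: int = 50, effect: float = 0.8) -> dict:
    """Planted logit-scale exposure effects: sensitivity and FDP at q<0.05."""
    sens, fdps = [], []
    for k in range(n_runs):
        em = EffectMap(exposure="PFOS",
                       total={i: effect for i in range(n_planted)})
        cohort, tab = _cohort_ewas(seed * 1000 + 500 + k, effect_map=em)
        sig = set(tab.index[tab["q_value"] < 0.05])
        planted = set(cohort.bs.betas.index[:n_planted])
        sens.append(len(sig & planted) / n_planted)
        fdps.append(len(sig - planted) / max(len(sig), 1))
    return {"sensitivity": float(np.mean(sens)),
            "mean_fdp": float(np.mean(fdps))}


# ---------------------------------------------------------------------------
# type-interaction estimator studies
# ---------------------------------------------------------------------------

def _paired_type_data(seed, delta, n=70, sigma_b=0.3, phi=(200.0, 150.0)):
    rng = np.random.default_rng(seed)
    E = rng.normal(size=n)
    sex = rng.binomial(1, 0.5, n).astype(float)
    b = rng.normal(scale=sigma_b, size=n)
    eta_m = -1.0 + 0.1 * sex + b
    eta_h = -2.2 + 0.1 * sex + delta * E + b
    ym = rng.beta(expit(eta_m) * phi[0], (1 - expit(eta_m)) * phi[0])
    yh = rng.beta(expit(eta_h) * phi[1], (1 - expit(eta_h)) * phi[1])
    y2 = np.clip(np.column_stack([ym, yh]), 1e-6, 1 - 1e-6)
    ones = np.ones(n)
    X = np.vstack([
        np.column_stack([ones, E, sex, np.zeros(n), np.zeros(n)]),
        np.column_stack([ones, E, sex, np.ones(n), E]),
    ])
    return X, y2


def type_interaction_recovery(reps: int = 300, seed: int = 0,
                              delta: float = 0.6, n: int = 70) -> dict:
    """Mean recovered Type x exposure coefficient over replicates."""
    names = ["intercept", "exposure", "sex", "type", "exposure:type"]
    ests = []
    for k in range(reps):
        X, y2 = _paired_type_data(seed * 10000 + k, delta, n=n)
        fit = fit_beta_mixed(X, y2, names=names)
        ests.append(float(fit.coef[4]))
    return {"mean_estimate": float(np.mean(ests)),
            "sd_estimate": float(np.std(ests)), "n_reps": reps}


def type_interaction_null(reps: int = 500, seed: int = 0, n: int = 70,
                          alpha: float = 0.05) -> dict:
    """Rejection rate of the interaction Wald test under the null."""
    names = ["intercept", "exposure", "sex", "type", "exposure:type"]
    rej = 0
    for k in range(reps):
        X, y2 = _paired_type_data(seed * 10000 + 5000 + k, 0.0, n=n)
        fit = fit_beta_mixed(X, y2, names=names)
        _, _, p = fit.term("exposure:type")
        rej += p < alpha
    return {"rejection_rate": rej / reps, "n_reps": reps}


# ---------------------------------------------------------------------------
# kernel mediation studies
# ---------------------------------------------------------------------------

def mediation_null_study(reps: int = 1000, seed: int = 0, n: int = 141,
                         n_sites: int = 20, alpha: float = 0.05) -> dict:
    """Type-I error of the kernel variance-component test under h = 0."""
    rng = np.random.default_rng(seed)
    rej = 0
    for _ in range(reps):
        X = np.column_stack([rng.poisson(1, n), rng.binomial(1, .07, n),
                             rng.binomial(1, .1, n)]).astype(float)
        E = rng.normal(size=n)
        M = rng.uniform(0, 1, size=(n, n_sites))
        Y = 0.3 * E + rng.normal(size=n)
        res = km_mediation_test(Y, E, X, M)
        rej += res.p_value < alpha
    return {"type_i_error": rej / reps, "n_reps": reps}


def mediation_power_study(reps: int = 300, seed: int = 0, n: int = 141,
                          n_sites: int = 10, alpha: float = 0.05) -> dict:
    """Power under strong planted mediation (~30% of outcome variance)."""
    rng = np.random.default_rng(seed + 1)
    rej = 0
    sign_ok = 0
    for _ in range(reps):
        X = np.column_stack([rng.poisson(1, n), rng.binomial(1, .07, n),
                             rng.binomial(1, .1, n)]).astype(float)
        E = rng.normal(size=n)
        M = 0.5 * E[:, None] + rng.normal(size=(n, n_sites))
        w = rng.normal(size=n_sites)
        signal = M @ w
        signal *= np.sqrt(0.30 / max(np.var(signal), 1e-12))
        Y = signal + rng.normal(size=n) * np.sqrt(0.70)
        res = km_mediation_test(Y, E, X, M)
        rej += res.p_value < alpha
        planted_indirect = 0.5 * w.sum() * np.sqrt(
            0.30 / max(np.var(M @ w), 1e-12))
        if planted_indirect != 0:
            sign_ok += np.sign(res.total_effect - res.direct_effect) == \
                np.sign(planted_indirect)
    return {"power": rej / reps, "n_reps": reps,
            "indirect_sign_agreement": sign_ok / reps}


# ---------------------------------------------------------------------------
# BH and deconvolution oracles
# ---------------------------------------------------------------------------

def bh_oracle_agreement(n_vectors: int = 1000, seed: int = 0) -> dict:
    """Max |q - q_bruteforce| over random p-vectors."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_vectors):
        p = rng.uniform(1e-12, 1, rng.integers(1, 50))
        m = len(p)
        order = np.argsort(p, kind="stable")
        ranked = p[order] * m / (np.arange(m) + 1)
        q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
        q_ref = np.empty(m)
        q_ref[order] = np.minimum(q_sorted, 1.0)
        worst = max(worst, float(np.abs(bh_adjust(p) - q_ref).max()))
    return {"max_abs_diff": worst, "n_vectors": n_vectors}


def deconvolution_recovery(seed: int = 0, n_samples: int = 50,
                           precision: float = 200.0) -> dict:
    """Cell-mixture recovery MAE under beta assay noise."""
    rng = np.random.default_rng(seed)
    panel = generate_reference_panel(CohortConfig(seed=seed))
    W = rng.dirichlet(np.ones(7) * 2, size=n_samples)
    samples = mix_reference_samples(panel, W, precision=precision,
                                    seed=seed + 1)
    est = deconvolve_cell_types(samples, panel)
    return {"mae": float(np.abs(est.to_numpy() - W).mean()),
            "n_samples": n_samples}
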
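"""Synthetic birth-cohort generator with known ground truth.

Emulates the structure of a prenatal-exposure methylation study: a panel of
correlated, right-skewed PFAS plasma concentrations left-censored at an
analytical LOD; maternal/infant covariates (parity, smoking, race
indicator, infant sex, seven cord-blood cell-type proportions, two batch
components); paired bisulfite / oxidative-bisulfite beta values generated
from true per-site (5-mC, 5-hmC) proportions with optional planted
exposure, sex-interaction and type-interaction effects on the logit scale;
and birth outcomes (gestational age in weeks, size-for-age z-score) with
planted direct and methylation-mediated exposure effects.

Default analyte distributions reproduce the published detection profile of
a nine-PFAS first-trimester panel (five well-detected analytes with
geometric means 3.2/5.3/1.1/0.37/0.12 ug/L, two moderately detected, two
poorly detected; LOD 0.1 ug/L throughout).  Default cohort sizes are 141
subjects with 70 paired BS/oxBS aliquots; the site count defaults to a
desk-scale 2,000.

Every draw flows from a single seed through per-stage child generators, so
identical configs give bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .arrayqc import MethylomeSet
from .exposures import ExposureTable

__all__ = [
    "AnalyteSpec", "EffectMap", "MediationSpec", "CellReferenceSpec",
    "CohortConfig", "SyntheticTruth", "SyntheticCohort", "generate_cohort",
    "generate_reference_panel", "mix_reference_samples", "default_analytes",
]

CELL_TYPES = ("CD4T", "CD8T", "Bcell", "Mono", "NK", "GranCell", "nRBC")
CELL_MEANS = (0.15, 0.07, 0.07, 0.08, 0.04, 0.55, 0.04)


@dataclass
class AnalyteSpec:
    name: str
    log_mean: float     # mean of ln(concentration), ug/L
    log_sd: float       # SD of ln(concentration)
    lod: float = 0.1    # ug/L


def default_analytes() -> list[AnalyteSpec]:
    """Nine-analyte PFAS panel matching the published detection profile."""
    ln = np.log
    return [
        AnalyteSpec("PFHxS", ln(3.2), ln(1.6)),
        AnalyteSpec("PFOS", ln(5.3), ln(1.7)),
        AnalyteSpec("PFOA", ln(1.1), ln(1.9)),
        AnalyteSpec("PFNA", ln(0.37), ln(1.8)),
        AnalyteSpec("PFDA", ln(0.12), ln(1.8)),
        AnalyteSpec("PFUnDA", -2.521, ln(1.8)),    # ~64% below LOD
        AnalyteSpec("MeFOSAA", -2.488, ln(1.8)),   # ~62% below LOD
        AnalyteSpec("PFOSA", -2.912, ln(1.8)),     # ~85% below LOD
        AnalyteSpec("PFHpA", -2.912, ln(1.8)),     # ~85% below LOD
    ]


@dataclass
class EffectMap:
    """Planted logit-scale effects of one exposure on methylation.

    Keys are site indices (0-based into the generated site list); values
    are coefficients per unit of the centered ln-concentration.
    ``total`` shifts the 5-mC linear predictor (and hence total
    methylation); ``sex`` multiplies exposure x male-sex; ``type`` shifts
    only the 5-hmC predictor, creating a type-specific exposure response.
    """

    exposure: str = "PFOS"
    total: dict = field(default_factory=dict)
    sex: dict = field(default_factory=dict)
    type: dict = field(default_factory=dict)

    def all_sites(self):
        return set(self.total) | set(self.sex) | set(self.type)


@dataclass
class MediationSpec:
    """Planted exposure -> methylation -> outcome pathway."""

    exposure: str = "PFNA"
    outcome: str = "gestational_age"
    mediator_sites: tuple = ()
    alpha: tuple = ()            # exposure -> mediator, logit scale
    theta: tuple = ()            # mediator -> outcome, per unit proportion
    layer: str = "5hmC"          # total | 5mC | 5hmC
    direct_effect: float = 0.0   # outcome units per ln-unit exposure
    outcome_noise_sd: float = 1.2


@dataclass
class CellReferenceSpec:
    cell_types: tuple = CELL_TYPES
    signature_sites_per_type: int = 50
    high: float = 0.85
    low: float = 0.08


@dataclass
class CohortConfig:
    n_subjects: int = 141
    n_paired: int = 70
    n_sites: int = 2000
    analytes: list = field(default_factory=default_analytes)
    exposure_correlation: float | np.ndarray = 0.3
    effect_map: EffectMap = field(default_factory=EffectMap)
    mediation: MediationSpec = field(default_factory=MediationSpec)
    cell_reference: CellReferenceSpec = field(default_factory=CellReferenceSpec)
    assay_precision: float = 200.0
    missing_smoking: float = 9 / 141
    missing_race: float = 6 / 141
    seed: int = 0

    def correlation_matrix(self) -> np.ndarray:
        k = len(self.analytes)
        if np.isscalar(self.exposure_correlation):
            R = np.full((k, k), float(self.exposure_correlation))
            np.fill_diagonal(R, 1.0)
        else:
            R = np.asarray(self.exposure_correlation, dtype=float)
        return R

    def validate(self):
        if self.n_subjects < 4:
            raise ValueError("n_subjects must be >= 4")
        if not (0 < self.n_paired <= self.n_subjects):
            raise ValueError("n_paired must be in (0, n_subjects]")
        if self.assay_precision <= 0:
            raise ValueError("assay precision must be positive")
        R = self.correlation_matrix()
        if R.shape != (len(self.analytes),) * 2:
            raise ValueError("correlation matrix shape mismatch")
        eig = np.linalg.eigvalsh((R + R.T) / 2)
        if eig.min() < -1e-10:
            raise ValueError("exposure correlation matrix is not PSD")
        bad = [s for s in (set(self.mediation.mediator_sites)
                           | self.effect_map.all_sites()) if s >= self.n_sites]
        if bad:
            raise ValueError(f"effect/mediator site indices out of range: {bad}")
        if len(self.mediation.mediator_sites) != len(self.mediation.alpha) or \
                len(self.mediation.mediator_sites) != len(self.mediation.theta):
            raise ValueError("mediation alpha/theta must match mediator_sites")

    def to_yaml(self, path):
        def plain(x):
            if isinstance(x, dict):
                return {plain(k): plain(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [plain(v) for v in x]
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            return x

        d = plain(asdict(self))
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["analytes"] = [AnalyteSpec(**a) for a in d.get("analytes", [])]
        if "effect_map" in d:
            em = d["effect_map"]
            for key in ("total", "sex", "type"):
                em[key] = {int(k): float(v) for k, v in em.get(key, {}).items()}
            d["effect_map"] = EffectMap(**em)
        if "mediation" in d:
            m = d["mediation"]
            for key in ("mediator_sites", "alpha", "theta"):
                m[key] = tuple(m.get(key, ()))
            d["mediation"] = MediationSpec(**m)
        if "cell_reference" in d:
            cr = d["cell_reference"]
            cr["cell_types"] = tuple(cr.get("cell_types", CELL_TYPES))
            d["cell_reference"] = CellReferenceSpec(**cr)
        return cls(**d)


@dataclass
class SyntheticTruth:
    true_mc: pd.DataFrame          # sites x subjects
    true_hmc: pd.DataFrame
    true_betas: dict               # (site_id, term) -> planted coefficient
    true_cell_props: pd.DataFrame  # subjects x 7
    true_indirect_effect: float
    true_direct_effect: float
    censored_mask: pd.DataFrame    # subjects x analytes
    uncensored_exposures: pd.DataFrame

    def to_json(self, path):
        d = {
            "true_betas": {f"{s}|{t}": v for (s, t), v in self.true_betas.items()},
            "true_indirect_effect": self.true_indirect_effect,
            "true_direct_effect": self.true_direct_effect,
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)


@dataclass
class SyntheticCohort:
    exposures: ExposureTable
    covariates: pd.DataFrame
    bs: MethylomeSet
    oxbs: MethylomeSet
    outcomes: pd.DataFrame
    truth: SyntheticTruth
    config: CohortConfig

    def write(self, outdir):
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.exposures.values.to_csv(out / "exposures.tsv", sep="\t")
        self.exposures.below_lod.to_csv(out / "below_lod.tsv", sep="\t")
        self.exposures.lod.to_frame("lod").to_csv(out / "lod.tsv", sep="\t")
        self.covariates.to_csv(out / "covariates.tsv", sep="\t")
        self.outcomes.to_csv(out / "outcomes.tsv", sep="\t")
        self.bs.betas.to_csv(out / "betas_bs.tsv", sep="\t")
        self.oxbs.betas.to_csv(out / "betas_oxbs.tsv", sep="\t")
        self.bs.annotation.to_csv(out / "annotation.tsv", sep="\t")
        self.truth.to_json(out / "truth.json")
        self.config.to_yaml(out / "config.yaml")


def _site_annotation(n_sites, rng):
    chroms, positions, genes = [], [], []
    per_chrom = int(np.ceil(n_sites / 22))
    i = 0
    for c in range(1, 23):
        pos = 1_000_000
        for _ in range(min(per_chrom, n_sites - i)):
            # mix of tight clusters (regional signal) and isolated probes
            gap = int(rng.integers(30, 280)) if rng.random() < 0.35 \
                else int(rng.integers(500, 20000))
            pos += gap
            chroms.append(f"chr{c}")
            positions.append(pos)
            genes.append(f"GENE{i // 5:04d}")
            i += 1
        if i >= n_sites:
            break
    sites = [f"cg{j:07d}" for j in range(n_sites)]
    return pd.DataFrame({"chrom": chroms, "pos": positions, "gene": genes},
                        index=pd.Index(sites, name="site"))


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw one complete synthetic study dataset (see module docstring)."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    r_exp, r_cov, r_meth, r_assay, r_out, r_miss, r_annot = (
        np.random.default_rng(s) for s in ss.spawn(7))

    n = config.n_subjects
    subjects = [f"S{i:04d}" for i in range(n)]
    analytes = [a.name for a in config.analytes]

    # --- exposures: multivariate log-normal, left-censored at the LOD
    R = config.correlation_matrix()
    L = np.linalg.cholesky(R + 1e-10 * np.eye(len(R)))
    Z = r_exp.standard_normal((n, len(analytes))) @ L.T
    mu = np.array([a.log_mean for a in config.analytes])
    sd = np.array([a.log_sd for a in config.analytes])
    conc = np.exp(mu + sd * Z)
    lods = pd.Series({a.name: a.lod for a in config.analytes})
    censored = conc < lods.to_numpy()
    observed = np.where(censored, np.nan, conc)
    exposures = ExposureTable(
        values=pd.DataFrame(observed, index=subjects, columns=analytes),
        below_lod=pd.DataFrame(censored, index=subjects, columns=analytes),
        lod=lods,
    )

    # --- covariates
    parity = np.clip(r_cov.poisson(1.0, n), 0, 4).astype(float)
    smoking = r_cov.binomial(1, 0.10, n).astype(float)
    race = r_cov.binomial(1, 0.07, n).astype(float)
    sex = r_cov.binomial(1, 0.489, n).astype(float)   # 1 = male
    cell = r_cov.dirichlet(np.array(CELL_MEANS) * 60.0, size=n)
    pcs = r_cov.standard_normal((n, 2))
    covariates = pd.DataFrame(
        np.column_stack([parity, smoking, race, sex, cell, pcs]),
        index=subjects,
        columns=["parity", "smoking", "race", "sex", *CELL_TYPES, "PC1", "PC2"],
    )
    true_cells = covariates[list(CELL_TYPES)].copy()

    # --- true methylation
    n_sites = config.n_sites
    annotation = _site_annotation(n_sites, r_annot)
    sites = annotation.index

    # total methylation is logit-linear in the covariates/exposure; the
    # 5-hmC fraction of that total follows its own (share) logit, so
    # p_m + p_h = total <= 1 by construction
    mix = r_meth.random(n_sites)
    base_t = np.where(mix < 0.3, r_meth.normal(-2.4, 0.5, n_sites),
                      np.where(mix < 0.6, r_meth.normal(2.0, 0.5, n_sites),
                               r_meth.normal(-0.2, 0.9, n_sites)))
    base_s = r_meth.normal(-1.9, 0.4, n_sites)   # hmc share ~ 0.08-0.25

    # per-site nuisance covariate coefficients (cell types dominate)
    cov_cols = ["parity", "smoking", "race", "sex", "CD4T", "CD8T",
                "GranCell", "nRBC", "PC1", "PC2"]
    sds = np.array([0.03, 0.05, 0.05, 0.05, 0.4, 0.4, 0.4, 0.4, 0.08, 0.08])
    C = covariates[cov_cols].to_numpy()
    C = C - C.mean(axis=0)
    coef_t = r_meth.standard_normal((n_sites, len(cov_cols))) * sds
    coef_s = r_meth.standard_normal((n_sites, len(cov_cols))) * (sds * 0.3)

    em = config.effect_map
    male = covariates["sex"].to_numpy()
    if em.all_sites():
        e_idx = analytes.index(em.exposure)
        E_centered = np.log(conc[:, e_idx]) - mu[e_idx]

    eta_t = base_t[:, None] + coef_t @ C.T          # sites x subjects
    eta_s = base_s[:, None] + coef_s @ C.T
    true_betas = {}
    for s_idx, b in em.total.items():
        eta_t[s_idx] += b * E_centered
        true_betas[(sites[s_idx], "exposure")] = b
    for s_idx, b in em.sex.items():
        eta_t[s_idx] += b * E_centered * male
        true_betas[(sites[s_idx], "exposure:sex")] = b
    med = config.mediation
    if med.mediator_sites:
        a_idx = analytes.index(med.exposure)
        E_med = np.log(conc[:, a_idx]) - mu[a_idx]
        for s_idx, a in zip(med.mediator_sites, med.alpha):
            if med.layer != "5hmC":
                eta_t[s_idx] += a * E_med
            true_betas[(sites[s_idx], f"mediator:{med.layer}")] = a

    total = expit(eta_t)
    share = expit(eta_s)
    p_h = total * share
    p_m = total * (1.0 - share)

    # type-interaction effects act directly on the 5-hmC logit while the
    # 5-mC logit stays fixed, so the planted value is exactly the contrast
    # in exposure slopes between the two methylation types
    def _shift_ph_logit(s_idx, shift):
        base = np.clip(p_h[s_idx], 1e-9, 1 - 1e-9)
        new = expit(np.log(base / (1 - base)) + shift)
        cap = 1.0 - p_m[s_idx] - 1e-9
        p_h[s_idx] = np.minimum(new, cap)

    for s_idx, b in em.type.items():
        _shift_ph_logit(s_idx, b * E_centered)
        true_betas[(sites[s_idx], "exposure:type")] = b
    if med.mediator_sites and med.layer == "5hmC":
        for s_idx, a in zip(med.mediator_sites, med.alpha):
            _shift_ph_logit(s_idx, a * E_med)

    true_mc = pd.DataFrame(p_m, index=sites, columns=subjects)
    true_hmc = pd.DataFrame(p_h, index=sites, columns=subjects)

    # --- assay noise: beta-distributed around the truth
    prec = config.assay_precision
    paired = subjects[:config.n_paired]

    def noisy(truth):
        t = np.clip(truth, 1e-6, 1 - 1e-6)
        if np.isinf(prec):
            return t.copy()
        return r_assay.beta(t * prec, (1 - t) * prec)

    bs_betas = pd.DataFrame(noisy(total), index=sites, columns=subjects)
    ox_betas = pd.DataFrame(noisy(p_m[:, :config.n_paired]), index=sites,
                            columns=paired)

    bs = MethylomeSet(betas=bs_betas, assay="BS", annotation=annotation)
    oxbs = MethylomeSet(betas=ox_betas, assay="oxBS", annotation=annotation)

    # --- outcomes with planted direct and mediated exposure effects
    ga = np.full(n, 39.5) + 0.1 * (parity - 1.0) - 0.3 * smoking
    fz = np.zeros(n) - 0.15 * smoking - 0.1 * race
    indirect = 0.0
    if med.mediator_sites or med.direct_effect:
        a_idx = analytes.index(med.exposure)
        E_med = np.log(conc[:, a_idx]) - mu[a_idx]
        target = ga if med.outcome == "gestational_age" else fz
        target += med.direct_effect * E_med
        layer_mat = {"total": total, "5mC": p_m, "5hmC": p_h}[med.layer]
        varE = float(np.var(E_med))
        for s_idx, th in zip(med.mediator_sites, med.theta):
            Mk = layer_mat[s_idx]
            target += th * (Mk - Mk.mean())
            indirect += th * float(np.cov(Mk, E_med)[0, 1]) / varE
    ga = ga + r_out.normal(0, med.outcome_noise_sd, n)
    fz = fz + r_out.normal(0, 0.9, n)
    outcomes = pd.DataFrame({"gestational_age": ga, "fenton_z": fz},
                            index=subjects)

    # --- missingness in categorical covariates
    cov_obs = covariates.copy()
    miss_s = r_miss.random(n) < config.missing_smoking
    miss_r = r_miss.random(n) < config.missing_race
    cov_obs.loc[miss_s, "smoking"] = np.nan
    cov_obs.loc[miss_r, "race"] = np.nan

    truth = SyntheticTruth(
        true_mc=true_mc, true_hmc=true_hmc, true_betas=true_betas,
        true_cell_props=true_cells,
        true_indirect_effect=float(indirect),
        true_direct_effect=float(med.direct_effect),
        censored_mask=exposures.below_lod.copy(),
        uncensored_exposures=pd.DataFrame(conc, index=subjects,
                                          columns=analytes),
    )
    return SyntheticCohort(exposures=exposures, covariates=cov_obs, bs=bs,
                           oxbs=oxbs, outcomes=outcomes, truth=truth,
                           config=config)


def generate_reference_panel(config: CohortConfig,
                             seed: int | None = None) -> pd.DataFrame:
    """Sites x cell-types reference methylation panel.

    Each cell type receives a block of signature sites that are highly
    methylated in that type and lowly methylated in the others, so the
    between-type range at every signature site is at least
    ``high - low`` (>= 0.5 with the defaults).
    """
    spec = config.cell_reference
    k = len(spec.cell_types)
    if k < 2:
        raise ValueError("need at least 2 cell types")
    m = spec.signature_sites_per_type
    if m < 7:
        raise ValueError("need >= 7 signature sites per cell type")
    rng = np.random.default_rng(config.seed + 7919 if seed is None else seed)
    n_rows = k * m
    panel = spec.low + rng.uniform(-0.04, 0.04, size=(n_rows, k))
    for t in range(k):
        rows = slice(t * m, (t + 1) * m)
        panel[rows, t] = spec.high + rng.uniform(-0.05, 0.05, size=m)
    panel = np.clip(panel, 0.0, 1.0)
    idx = [f"ref{t}_{j:03d}" for t in range(k) for j in range(m)]
    return pd.DataFrame(panel, index=pd.Index(idx, name="site"),
                        columns=list(spec.cell_types))


def mix_reference_samples(panel: pd.DataFrame, weights: np.ndarray,
                          precision: float = np.inf,
                          seed: int = 0) -> pd.DataFrame:
    """Synthesize mixture samples from a reference panel.

    ``weights`` is samples x cell-types on the simplex; beta-distributed
    assay noise at ``precision`` is added unless precision is infinite.
    """
    rng = np.random.default_rng(seed)
    W = np.asarray(weights, dtype=float)
    mix = panel.to_numpy() @ W.T
    if not np.isinf(precision):
        t = np.clip(mix, 1e-6, 1 - 1e-6)
        mix = rng.beta(t * precision, (1 - t) * precision)
    return pd.DataFrame(mix, index=panel.index,
                        columns=[f"mix{j}" for j in range(W.shape[0])])
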
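"""End-to-end orchestration: simulate -> exposures -> QC -> decomposition ->
EWAS families -> regions -> mediation, with a machine-readable run report.

All randomness flows from the run seed through per-stage derived seeds, so
an identical config gives a byte-identical report.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .arrayqc import clamp_proportions
from .ewas import (ModelSpec, aggregate_regions, genomic_inflation,
                   interaction_screen_stratify, regions_to_bed, run_ewas,
                   run_type_interaction_ewas)
from .exposures import (analysis_variables, classify_all,
                        impute_missing_covariates)
from .mediation import (gene_wise_and_global_mediation, outcome_exposure_models,
                        screen_mediators, site_outcome_pvalues)
from .mlml import build_long_matrix, estimate_proportions, filter_low_total
from .synthetic import CohortConfig, generate_cohort

__all__ = ["RunConfig", "run_pipeline", "write_reports"]

TOTAL_COVARIATES = ("parity", "smoking", "race", "sex", "CD4T", "CD8T",
                    "GranCell", "nRBC", "PC1", "PC2")
STRAT_COVARIATES = tuple(c for c in TOTAL_COVARIATES if c != "sex")


@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    exposures_to_model: tuple | None = None   # None = all retained analytes
    q_total: float = 0.05
    q_sex_screen: float = 0.05
    q_type_screen: float = 0.2
    q_stratified: float = 0.05
    mediation_thresholds: tuple = (0.05, 0.1, 0.05)
    region_bin: int = 310
    region_trigger: int = 1000
    sex_interaction: bool = True
    type_interaction_sites: int = 50   # cap for the per-site mixed model
    outdir: str | None = None
    seed: int = 0

    def validate(self):
        for t in (self.q_total, self.q_sex_screen, self.q_type_screen,
                  self.q_stratified, *self.mediation_thresholds):
            if not (0 < t < 1):
                raise ValueError(f"threshold {t} outside (0, 1)")

    def hash(self) -> str:
        payload = json.dumps(
            {k: str(v) for k, v in self.__dict__.items() if k != "outdir"},
            sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage on a synthetic cohort; returns the run report."""
    report, _ = run_pipeline_results(config)
    return report


def run_pipeline_results(config: RunConfig):
    """Execute every stage; returns (report, results) with all tables."""
    config.validate()
    config.cohort.seed = config.seed
    report: dict = {"config_hash": config.hash(), "version": __version__,
                    "seed": config.seed, "stages": {}}
    results: dict = {}

    # --- stage: simulate
    cohort = generate_cohort(config.cohort)
    results["cohort"] = cohort
    report["stages"]["simulate"] = {
        "n_subjects": int(config.cohort.n_subjects),
        "n_paired": int(config.cohort.n_paired),
        "n_sites": int(config.cohort.n_sites),
    }

    # --- stage: exposures
    classes = classify_all(cohort.exposures)
    evars = analysis_variables(cohort.exposures, classes)
    covariates = impute_missing_covariates(
        cohort.covariates, seed=config.seed + 1,
        columns=["smoking", "race"])
    results["classes"] = classes
    results["exposure_vars"] = evars
    report["stages"]["exposures"] = {
        "n_continuous": int((classes["class"] == "continuous").sum()),
        "n_categorical": int((classes["class"] == "categorical").sum()),
        "n_excluded": int((classes["class"] == "excluded").sum()),
    }

    # --- stage: qc (synthetic betas are clean; clamp into the open interval)
    bs = clamp_proportions(cohort.bs)
    oxbs = clamp_proportions(cohort.oxbs)
    annotation = cohort.bs.annotation

    # --- stage: decomposition on the paired subset
    paired = list(oxbs.samples)
    dec = estimate_proportions(bs.betas[paired].to_numpy(),
                               oxbs.betas[paired].to_numpy())
    mc = pd.DataFrame(dec.p_m, index=bs.sites, columns=paired)
    hmc = pd.DataFrame(dec.p_h, index=bs.sites, columns=paired)
    mc, hmc, removed = filter_low_total(mc, hmc, threshold=0.1)
    # MLML boundary zeros are clamped at 1e-3 (below assay resolution)
    # rather than 1e-6: the logit outliers otherwise dominate per-type fits
    mc = clamp_proportions(mc, eps=1e-3)
    hmc = clamp_proportions(hmc, eps=1e-3)
    long = build_long_matrix(mc, hmc)
    results["mc"], results["hmc"], results["long"] = mc, hmc, long
    report["stages"]["decompose"] = {
        "entries_at_boundary": int(dec.boundary.sum()),
        "sites_removed_low_total": int(len(removed)),
        "sites_retained": int(len(mc)),
        "long_rows_per_site": int(2 * len(paired)),
    }

    # --- stage: EWAS families
    exposures_to_model = config.exposures_to_model or [
        a for a in classes.index if classes.loc[a, "class"] != "excluded"]
    ewas_tabs: dict = {}
    lambdas = {}
    sig_counts = {}
    for analyte in exposures_to_model:
        if analyte not in evars.columns:
            continue
        exp_series = evars[analyte]
        spec = ModelSpec(response="total", exposure=analyte,
                         covariates=TOTAL_COVARIATES)
        tab = run_ewas(bs.betas, exp_series, covariates, spec,
                       annotation=annotation)
        ewas_tabs[(analyte, "total")] = tab
        ok = tab["p_value"].dropna()
        lambdas[analyte] = genomic_inflation(ok.to_numpy()) if len(ok) >= 100 else np.nan
        sig_counts[analyte] = int((tab["q_value"] < config.q_total).sum())

        if config.sex_interaction:
            spec_sx = ModelSpec(response="total", exposure=analyte,
                                covariates=TOTAL_COVARIATES, interaction="sex")
            inter = run_ewas(bs.betas, exp_series, covariates, spec_sx,
                             annotation=annotation)

            def _strat_fitter(sex_value):
                def fit(sites):
                    keep = covariates["sex"] == sex_value
                    sub = exp_series[keep.index[keep]]
                    spec_s = ModelSpec(response="total", exposure=analyte,
                                       covariates=STRAT_COVARIATES)
                    return run_ewas(bs.betas.loc[sites], sub,
                                    covariates, spec_s, annotation=annotation)
                return fit

            strata = interaction_screen_stratify(
                inter, config.q_sex_screen,
                {"female": _strat_fitter(0.0), "male": _strat_fitter(1.0)})
            ewas_tabs[(analyte, "sex_interaction")] = inter
            for name, stab in strata.items():
                ewas_tabs[(analyte, f"sex_{name}")] = stab

    results["ewas"] = ewas_tabs
    report["stages"]["ewas_total"] = {
        "lambda": {k: round(float(v), 4) for k, v in lambdas.items()},
        "significant_sites": sig_counts,
    }

    # --- stage: type-interaction family (capped site count)
    med_exposure = config.cohort.mediation.exposure
    type_exposures = [med_exposure] if med_exposure in evars.columns \
        else list(evars.columns[:1])
    type_tabs = {}
    paired_cov = covariates.loc[paired]
    for analyte in type_exposures:
        sites_cap = mc.index[:config.type_interaction_sites]
        spec_t = ModelSpec(response="long-type", exposure=analyte,
                           covariates=TOTAL_COVARIATES, interaction="type",
                           random_intercept=True, dispersion="per-type")
        inter = run_type_interaction_ewas(
            mc.loc[sites_cap], hmc.loc[sites_cap],
            evars.loc[paired, analyte], paired_cov, spec_t,
            annotation=annotation)

        def _layer_fitter(layer_mat):
            def fit(sites):
                spec_s = ModelSpec(response="5mC", exposure=analyte,
                                   covariates=TOTAL_COVARIATES)
                return run_ewas(layer_mat.loc[sites], evars.loc[paired, analyte],
                                paired_cov, spec_s, annotation=annotation)
            return fit

        strata = interaction_screen_stratify(
            inter, config.q_type_screen,
            {"5mC": _layer_fitter(mc), "5hmC": _layer_fitter(hmc)})
        type_tabs[(analyte, "type_interaction")] = inter
        for name, stab in strata.items():
            type_tabs[(analyte, name)] = stab
    results["type_ewas"] = type_tabs
    report["stages"]["ewas_type"] = {
        "screened": {a: int((t["q_value"] < config.q_type_screen).sum())
                     for (a, fam), t in type_tabs.items()
                     if fam == "type_interaction"},
    }

    # --- stage: regions (triggered by large significant sets)
    region_tabs = {}
    for (analyte, fam), tab in {**ewas_tabs, **type_tabs}.items():
        n_sig = int((tab["q_value"] < config.q_total).sum())
        if n_sig > config.region_trigger:
            vals = bs.betas if fam.startswith("total") else None
            region_tabs[(analyte, fam)] = aggregate_regions(
                tab, annotation, bin_width=config.region_bin, values=vals)
    results["regions"] = region_tabs
    report["stages"]["regions"] = {f"{a}:{f}": len(t)
                                   for (a, f), t in region_tabs.items()}

    # --- stage: mediation
    outcome_tab = outcome_exposure_models(cohort.outcomes, evars, covariates)
    layer_mats = {"total": bs.betas, "5mC": mc, "5hmC": hmc}
    ewas_by_layer = {}
    for (analyte, fam), tab in ewas_tabs.items():
        if fam == "total":
            ewas_by_layer[(analyte, "total")] = tab
    for (analyte, fam), tab in type_tabs.items():
        if fam in ("5mC", "5hmC"):
            ewas_by_layer[(analyte, fam)] = tab

    q1, p2, p3 = config.mediation_thresholds
    site_p = {}
    for _, row in outcome_tab[outcome_tab["p_value"] < p2].iterrows():
        e, o = row["exposure"], row["outcome"]
        for (ee, layer), tab in ewas_by_layer.items():
            if ee != e:
                continue
            tier1 = tab.index[tab["q_value"] < q1]
            if len(tier1) == 0:
                continue
            meth = layer_mats[layer]
            common = cohort.outcomes.index.intersection(meth.columns)
            site_p[(e, o, layer)] = site_outcome_pvalues(
                cohort.outcomes.loc[common, o],
                meth.loc[tier1, common], covariates.loc[common])
    candidates = screen_mediators(ewas_by_layer, outcome_tab, site_p,
                                  thresholds=config.mediation_thresholds,
                                  gene_labels=annotation["gene"])
    mediation_tab = gene_wise_and_global_mediation(
        candidates, cohort.outcomes, evars, covariates, layer_mats)
    results["outcome_models"] = outcome_tab
    results["mediation"] = mediation_tab
    report["stages"]["mediation"] = {
        "tier2_exposure_outcome_pairs": int((outcome_tab["p_value"] < p2).sum()),
        "candidate_sets": len(candidates),
        "significant_sets": int((mediation_tab["q_value"] < 0.05).sum())
        if len(mediation_tab) else 0,
    }

    if config.outdir:
        write_reports(results, report, config.outdir)
    results["report"] = report
    return report, results


def write_reports(results: dict, report: dict, outdir):
    """Write TSV result tables, BED region exports, and the JSON report."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for (analyte, fam), tab in results.get("ewas", {}).items():
        tab.to_csv(out / f"ewas_{analyte}_{fam}.tsv", sep="\t")
    for (analyte, fam), tab in results.get("type_ewas", {}).items():
        tab.to_csv(out / f"ewas_{analyte}_{fam}.tsv", sep="\t")
    for (analyte, fam), tab in results.get("regions", {}).items():
        tab.to_csv(out / f"regions_{analyte}_{fam}.tsv", sep="\t", index=False)
        regions_to_bed(tab).to_csv(out / f"regions_{analyte}_{fam}.bed",
                                   sep="\t", header=False, index=False)
    if "outcome_models" in results:
        results["outcome_models"].to_csv(out / "outcome_models.tsv",
                                         sep="\t", index=False)
    if "mediation" in results and len(results["mediation"]):
        results["mediation"].to_csv(out / "mediation.tsv", sep="\t", index=False)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    # plain-text count summary
    with open(out / "summary.txt", "w") as fh:
        fh.write("pipeline run summary\n")
        for stage, vals in report["stages"].items():
            fh.write(f"[{stage}]\n")
            for k, v in vals.items():
                fh.write(f"  {k}: {v}\n")
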
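"""Site-wise beta-regression EWAS with interaction screens and diagnostics.

Three model families are supported, mirroring the analysis design for a
prenatal-exposure methylation study:

* total methylation: beta regression of each CpG's proportion on the
  exposure, adjusting for parity, smoking, race, infant sex, four cell-type
  proportions and two batch components;
* sex interaction: the same model plus a sex x exposure term, with
  follow-up models stratified by sex (dropping the sex covariate) at
  screened sites;
* type interaction: a beta mixed model on the long 5-mC/5-hmC matrix with a
  subject random intercept, a Type indicator, a Type x exposure term and a
  separate precision per type, with follow-up per-type models at screened
  sites.

Inference helpers: genomic inflation factor, Benjamini-Hochberg adjustment,
and correlation-corrected Stouffer aggregation of nearby sites into
regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .betamixed import TypeInteractionFit, fit_beta_mixed
from .betareg import fit_betareg_batch

__all__ = [
    "ModelSpec", "SiteFit", "fit_beta_regression", "fit_type_interaction",
    "run_ewas", "run_type_interaction_ewas", "interaction_screen_stratify",
    "genomic_inflation", "bh_adjust", "aggregate_regions", "build_design",
]

CHI2_MEDIAN_1DF = stats.chi2.ppf(0.5, 1)   # 0.4549364...


@dataclass
class ModelSpec:
    """Declarative description of one EWAS model family."""

    response: str = "total"            # total | 5mC | 5hmC | long-type
    exposure: str = "exposure"
    covariates: tuple = ("parity", "smoking", "race", "sex",
                         "CD4T", "CD8T", "GranCell", "nRBC", "PC1", "PC2")
    interaction: str = "none"          # none | sex | type
    random_intercept: bool = False
    dispersion: str = "common"         # common | per-type
    q_threshold: float = 0.05

    def __post_init__(self):
        if self.interaction == "type" and not self.random_intercept:
            self.random_intercept = True
        if self.random_intercept and self.response != "long-type":
            raise ValueError("random intercept requires the long-type response")


@dataclass
class SiteFit:
    """One fitted site: per-term estimates on the logit scale."""

    site: str
    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    pvalues: np.ndarray
    phi: float | np.ndarray
    loglik: float
    converged: bool
    sigma2_b: float | None = None

    def conf_int(self, level=0.95):
        z = stats.norm.ppf(0.5 + level / 2)
        return self.coef - z * self.se, self.coef + z * self.se

    def term(self, name):
        j = self.names.index(name)
        return self.coef[j], self.se[j], self.pvalues[j]


def build_design(exposure: pd.Series, covariates: pd.DataFrame,
                 interaction_with: str | None = None):
    """Assemble [intercept, exposure, covariates, (interaction)] design."""
    subjects = exposure.index
    cov = covariates.loc[subjects]
    cols = {"intercept": np.ones(len(subjects)), "exposure": exposure.to_numpy(dtype=float)}
    for c in cov.columns:
        cols[c] = cov[c].to_numpy(dtype=float)
    if interaction_with is not None:
        cols[f"exposure:{interaction_with}"] = (
            cols["exposure"] * cov[interaction_with].to_numpy(dtype=float))
    X = np.column_stack(list(cols.values()))
    return X, list(cols.keys())


def fit_beta_regression(y, X, names=None, site: str = "site") -> SiteFit:
    """Single-site beta regression (logit mean link, log-scale precision).

    Thin wrapper over the vectorized batch engine; non-convergence is
    flagged on the result, not raised.
    """
    res = fit_betareg_batch(np.asarray(X, float), np.asarray(y, float)[:, None],
                            names=names)
    return SiteFit(
        site=site,
        names=res.names,
        coef=res.coef[:, 0],
        se=res.se[:, 0],
        pvalues=res.pvalues()[:, 0],
        phi=float(res.phi[0]),
        loglik=float(res.loglik[0]),
        converged=bool(res.converged[0]),
    )


def fit_type_interaction(y2, X_long, names=None, site: str = "site",
                         n_nodes: int = 15) -> SiteFit:
    """Beta mixed model for one site's paired 5-mC/5-hmC observations."""
    fit: TypeInteractionFit = fit_beta_mixed(X_long, y2, names=names,
                                             n_nodes=n_nodes)
    return SiteFit(
        site=site,
        names=fit.names,
        coef=fit.coef,
        se=fit.se,
        pvalues=fit.pvalues,
        phi=fit.phi,
        loglik=fit.loglik,
        converged=fit.converged,
        sigma2_b=fit.sigma2_b,
    )


def _result_table(sites, coef, se, pvals, converged, annotation=None,
                  q_over_converged=True):
    tab = pd.DataFrame({
        "site": sites,
        "estimate": coef,
        "se": se,
        "ci_lower": coef - 1.96 * se,
        "ci_upper": coef + 1.96 * se,
        "p_value": pvals,
        "converged": converged,
    }).set_index("site")
    tab["exp_estimate"] = np.exp(tab["estimate"])
    tab["q_value"] = np.nan
    ok = tab["converged"] & tab["p_value"].notna() if q_over_converged \
        else tab["p_value"].notna()
    if ok.any():
        tab.loc[ok, "q_value"] = bh_adjust(tab.loc[ok, "p_value"].to_numpy())
    if annotation is not None:
        tab = tab.join(annotation, how="left")
    return tab


def run_ewas(betas: pd.DataFrame, exposure: pd.Series,
             covariates: pd.DataFrame, spec: ModelSpec,
             annotation: pd.DataFrame | None = None,
             term: str | None = None) -> pd.DataFrame:
    """Fit one beta regression per CpG site and BH-adjust the target term.

    ``betas`` is sites x subjects with values strictly inside (0, 1);
    subjects must align with ``exposure`` and ``covariates``.  The reported
    term defaults to the exposure coefficient, or the interaction
    coefficient when the spec declares one.  Non-converged sites are
    excluded from the BH denominator; a run-level warning is attached via
    ``result.attrs`` when more than 20% fail.
    """
    subjects = exposure.index
    if not set(subjects).issubset(betas.columns):
        raise ValueError("exposure subjects missing from the beta matrix")
    inter = spec.interaction if spec.interaction in ("sex",) else None
    X, names = build_design(exposure, covariates[list(spec.covariates)],
                            interaction_with=inter)
    if term is None:
        term = f"exposure:{inter}" if inter else "exposure"
    j = names.index(term)
    Y = betas[subjects].T.to_numpy(dtype=float)
    res = fit_betareg_batch(X, Y, names=names)
    pv = res.pvalues()
    tab = _result_table(betas.index, res.coef[j], res.se[j], pv[j],
                        res.converged, annotation)
    frac_bad = 1.0 - res.converged.mean()
    tab.attrs["term"] = term
    tab.attrs["n_subjects"] = len(subjects)
    tab.attrs["frac_nonconverged"] = float(frac_bad)
    if frac_bad > 0.20:
        tab.attrs["warning"] = f"{frac_bad:.1%} of sites failed to converge"
    return tab


def run_type_interaction_ewas(mc: pd.DataFrame, hmc: pd.DataFrame,
                              exposure: pd.Series, covariates: pd.DataFrame,
                              spec: ModelSpec,
                              annotation: pd.DataFrame | None = None,
                              n_nodes: int = 15) -> pd.DataFrame:
    """Beta mixed model per site on the paired 5-mC/5-hmC data.

    Reports the Type x exposure coefficient.  Sites whose optimizer fails
    are flagged and excluded from the BH denominator with a logged reason.
    """
    subjects = exposure.index
    Xbase, names = build_design(exposure, covariates[list(spec.covariates)])
    n = len(subjects)
    X0 = np.column_stack([Xbase, np.zeros(n), np.zeros(n)])
    X1 = np.column_stack([Xbase, np.ones(n), Xbase[:, 1]])
    X_long = np.vstack([X0, X1])
    names_long = names + ["type", "exposure:type"]
    j = names_long.index("exposure:type")

    rows = []
    for site in mc.index:
        y2 = np.column_stack([mc.loc[site, subjects], hmc.loc[site, subjects]])
        try:
            fit = fit_type_interaction(y2, X_long, names=names_long,
                                       site=site, n_nodes=n_nodes)
            rows.append((site, fit.coef[j], fit.se[j], fit.pvalues[j],
                         fit.converged))
        except Exception:
            rows.append((site, np.nan, np.nan, np.nan, False))
    arr = pd.DataFrame(rows, columns=["site", "c", "s", "p", "ok"])
    tab = _result_table(arr["site"], arr["c"].to_numpy(), arr["s"].to_numpy(),
                        arr["p"].to_numpy(), arr["ok"].to_numpy(), annotation)
    tab.attrs["term"] = "exposure:type"
    return tab


def interaction_screen_stratify(interaction_results: pd.DataFrame,
                                q_screen: float,
                                strata_fitters: dict) -> dict:
    """Stratified follow-up at sites passing the interaction screen.

    ``strata_fitters`` maps stratum name -> callable(site_list) returning a
    result table for those sites (e.g. a sex-stratified fit without the sex
    covariate, or a per-methylation-type fit).  BH within each stratum is
    recomputed over the screened set only.  An empty screened set yields
    empty tables, not an error.
    """
    screened = interaction_results.index[
        interaction_results["q_value"] < q_screen]
    out = {}
    for stratum, fitter in strata_fitters.items():
        if len(screened) == 0:
            out[stratum] = interaction_results.iloc[0:0].copy()
            continue
        tab = fitter(list(screened))
        ok = tab["converged"] & tab["p_value"].notna()
        tab["q_value"] = np.nan
        if ok.any():
            tab.loc[ok, "q_value"] = bh_adjust(tab.loc[ok, "p_value"].to_numpy())
        out[stratum] = tab
    return out


def genomic_inflation(pvals) -> float:
    """Genomic inflation factor lambda.

    Transforms each p-value to its 1-df chi-squared quantile and divides
    the observed median by the null median (0.4549...).  Well-calibrated
    models give lambda near 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size < 100:
        raise ValueError("need at least 100 p-values for a stable lambda")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / CHI2_MEDIAN_1DF)


def bh_adjust(pvals):
    """Benjamini-Hochberg step-up q-values (monotone, q >= p)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def aggregate_regions(site_results: pd.DataFrame,
                      annotation: pd.DataFrame,
                      bin_width: int = 310,
                      values: pd.DataFrame | None = None) -> pd.DataFrame:
    """Combine nearby sites into regions with a correlation-aware Stouffer test.

    Consecutive same-chromosome sites at most ``bin_width`` bp apart form a
    region.  Each site's p-value maps to z = Phi^{-1}(1 - p); the region
    statistic is sum(z) / sqrt(m + m(m-1) * rbar), where rbar is the mean
    pairwise correlation of the constituent sites' methylation values
    (``values``, sites x subjects; rbar = 0 when not supplied), an
    effective-size correction for locally correlated probes.  Region
    p-values are BH-adjusted across regions.  Positions are 1-based
    inclusive.
    """
    known = site_results.index.intersection(annotation.index)
    skipped = site_results.index.difference(annotation.index)
    res = site_results.loc[known].drop(columns=["chrom", "pos"],
                                       errors="ignore")
    res = res.join(annotation.loc[known, ["chrom", "pos"]])
    res = res.dropna(subset=["p_value"])
    res = res.sort_values(["chrom", "pos"])

    regions = []
    for chrom, grp in res.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        breaks = np.where(np.diff(pos) > bin_width)[0]
        start = 0
        for b in list(breaks) + [len(pos) - 1]:
            block = grp.iloc[start:b + 1]
            start = b + 1
            m = len(block)
            z = stats.norm.isf(block["p_value"].to_numpy())
            rbar = 0.0
            if values is not None and m > 1:
                V = values.loc[block.index].to_numpy(dtype=float)
                C = np.corrcoef(V)
                iu = np.triu_indices(m, 1)
                rbar = float(np.nanmean(C[iu]))
            denom = np.sqrt(m + m * (m - 1) * max(rbar, 0.0))
            p_region = float(stats.norm.sf(z.sum() / denom))
            regions.append({
                "chrom": chrom,
                "start": int(block["pos"].min()),
                "end": int(block["pos"].max()),
                "n_probes": m,
                "p_value": min(max(p_region, np.nextafter(0, 1)), 1.0),
                "sites": ";".join(block.index),
            })
    out = pd.DataFrame(regions)
    if len(out):
        out["q_value"] = bh_adjust(out["p_value"].to_numpy())
        out = out.sort_values("p_value").reset_index(drop=True)
    else:
        out = pd.DataFrame(columns=["chrom", "start", "end", "n_probes",
                                    "p_value", "sites", "q_value"])
    out.attrs["skipped_sites"] = list(skipped)
    return out


def regions_to_bed(regions: pd.DataFrame) -> pd.DataFrame:
    """Export regions as BED (0-based half-open start, 1-based end)."""
    bed = pd.DataFrame({
        "chrom": regions["chrom"],
        "start": regions["start"].astype(int) - 1,
        "end": regions["end"].astype(int),
        "name": [f"region_{i}" for i in range(len(regions))],
        "score": -np.log10(regions["p_value"].clip(lower=1e-300)),
    })
    return bed
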
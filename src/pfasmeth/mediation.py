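"""Kernel-machine mediation of exposure effects on birth outcomes.

The mediation pathway exposure -> CpG methylation -> birth outcome is
tested set-wise.  Candidate CpG sets are assembled through a three-tier
screen (exposure-methylation q < 0.05; exposure-outcome p < 0.1;
methylation-outcome p < 0.05), which establishes the exposure->mediator
path, and the mediator->outcome path is then tested jointly with a
variance-component score test:

    Y = X gamma + E alpha_d + h(M) + eps,

where h lives in the RKHS of a kernel over the mediator block M.  Under
H0: h = 0 the score statistic Q = r' K r / (2 sigma^2) (r the null-model
residuals) follows a mixture of chi-squares, approximated by Satterthwaite
moment matching (default) or the Liu three-moment method.  Because tier-1
screening established the exposure->M association, a small variance-
component p-value is interpretable as a joint-significance mediation test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .ewas import bh_adjust

__all__ = [
    "OutcomeModelResult", "MediationCandidateSet", "MediationResult",
    "outcome_exposure_models", "site_outcome_pvalues", "screen_mediators",
    "kernel_matrix", "km_mediation_test", "gene_wise_and_global_mediation",
]

OUTCOME_COVARIATES = ("parity", "race", "smoking")


@dataclass
class MediationCandidateSet:
    exposure: str
    outcome: str
    layer: str                      # total | 5mC | 5hmC
    sites: list[str]
    genes: dict[str, str] = field(default_factory=dict)   # site -> gene label
    provenance: dict = field(default_factory=dict)


@dataclass
class MediationResult:
    exposure: str
    outcome: str
    layer: str
    group: str                      # gene label or "all"
    n_sites: int
    statistic: float
    p_value: float
    q_value: float | None
    total_effect: float
    direct_effect: float
    tau_boundary: bool = False


@dataclass
class OutcomeModelResult:
    exposure: str
    outcome: str
    coef: float
    se: float
    p_value: float
    n: int


def _check_collinear(X: pd.DataFrame):
    arr = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        # identify columns predictable from the rest
        bad = []
        for j, c in enumerate(X.columns):
            others = np.delete(arr, j, axis=1)
            proj, *_ = np.linalg.lstsq(others, arr[:, j], rcond=None)
            if np.allclose(others @ proj, arr[:, j], atol=1e-8):
                bad.append(c)
        raise ValueError(f"collinear design columns: {bad}")


def outcome_exposure_models(outcomes: pd.DataFrame,
                            exposure_vars: pd.DataFrame,
                            covariates: pd.DataFrame) -> pd.DataFrame:
    """OLS of each birth outcome on each exposure plus parity, race, smoking.

    Returns one row per (exposure, outcome) with the exposure coefficient,
    its SE and p-value - the tier-2 screening inputs for mediation.
    """
    cov = covariates[list(OUTCOME_COVARIATES)]
    rows = []
    for e in exposure_vars.columns:
        x = exposure_vars[e]
        if float(np.nanvar(x)) == 0.0:
            raise ValueError(f"exposure {e!r} has zero variance")
        for o in outcomes.columns:
            df = pd.concat([outcomes[o], x.rename("exposure"), cov], axis=1).dropna()
            X = sm.add_constant(df[["exposure", *OUTCOME_COVARIATES]])
            _check_collinear(X)
            fit = sm.OLS(df[o], X).fit()
            rows.append(OutcomeModelResult(e, o, float(fit.params["exposure"]),
                                           float(fit.bse["exposure"]),
                                           float(fit.pvalues["exposure"]),
                                           int(fit.nobs)))
    return pd.DataFrame([r.__dict__ for r in rows])


def site_outcome_pvalues(outcome: pd.Series, methylation: pd.DataFrame,
                         covariates: pd.DataFrame) -> pd.Series:
    """Tier-3 screen: p-value of each CpG site in an OLS of the outcome on
    site methylation plus the outcome-model covariates."""
    cov = covariates.loc[outcome.index, list(OUTCOME_COVARIATES)]
    base = sm.add_constant(cov.to_numpy(dtype=float))
    y = outcome.to_numpy(dtype=float)
    out = {}
    for site in methylation.index:
        m = methylation.loc[site, outcome.index].to_numpy(dtype=float)
        X = np.column_stack([base, m])
        fit = sm.OLS(y, X).fit()
        out[site] = float(fit.pvalues[-1])
    return pd.Series(out, name="p_site_outcome")


def screen_mediators(ewas_results: dict,
                     outcome_models: pd.DataFrame,
                     site_outcome_p: dict,
                     thresholds=(0.05, 0.1, 0.05),
                     gene_labels: pd.Series | None = None) -> list[MediationCandidateSet]:
    """Three-tier mediation screen.

    Parameters
    ----------
    ewas_results : {(exposure, layer): result table with a q_value column}
    outcome_models : table from :func:`outcome_exposure_models`
    site_outcome_p : {(exposure, outcome, layer): Series of tier-3 p-values}
    thresholds : (q1, p2, p3)
        Tier 1: exposure-methylation q; tier 2: exposure-outcome p;
        tier 3: methylation-outcome p.
    """
    q1, p2, p3 = thresholds
    passing = outcome_models[outcome_models["p_value"] < p2]
    out = []
    for _, row in passing.iterrows():
        e, o = row["exposure"], row["outcome"]
        for (ee, layer), tab in ewas_results.items():
            if ee != e:
                continue
            tier1 = tab.index[tab["q_value"] < q1]
            if len(tier1) == 0:
                continue
            key = (e, o, layer)
            if key not in site_outcome_p:
                raise ValueError(f"missing tier-3 p-values for {key}")
            p3s = site_outcome_p[key].reindex(tier1)
            sites = list(p3s.index[p3s < p3])
            if not sites:
                continue
            genes = {}
            if gene_labels is not None:
                genes = {s: gene_labels.get(s, "") for s in sites}
            out.append(MediationCandidateSet(
                exposure=e, outcome=o, layer=layer, sites=sites, genes=genes,
                provenance={"tier1_q": q1, "tier2_p": float(row["p_value"]),
                            "tier3_p": p3},
            ))
    return out


def kernel_matrix(M: np.ndarray, kernel: str = "gaussian",
                  bandwidth: float | None = None) -> np.ndarray:
    """Subject x subject kernel over a mediator block (subjects x sites).

    Gaussian: K = exp(-d^2 / (2 h^2)) with h the median nonzero pairwise
    Euclidean distance (the median heuristic) unless given.  Linear:
    centered M M'.  Both are symmetric PSD.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    if np.isnan(M).any():
        raise ValueError("mediator block contains missing values")
    if kernel == "linear":
        Mc = M - M.mean(axis=0)
        return Mc @ Mc.T
    if kernel != "gaussian":
        raise ValueError(f"unknown kernel {kernel!r}")
    d = pdist(M)
    if bandwidth is None:
        nz = d[d > 0]
        bandwidth = float(np.median(nz)) if nz.size else 1.0
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    D = squareform(d)
    return np.exp(-(D**2) / (2.0 * bandwidth**2))


def _null_model(Y, X, E):
    W = np.column_stack([np.ones(len(Y)), X, E])
    if np.linalg.matrix_rank(W) < W.shape[1]:
        raise ValueError("singular null-model design (X, E)")
    WtW_inv = np.linalg.inv(W.T @ W)
    H = W @ WtW_inv @ W.T
    P0 = np.eye(len(Y)) - H
    gamma = WtW_inv @ (W.T @ Y)
    r = Y - W @ gamma
    df = len(Y) - W.shape[1]
    sigma2 = float(r @ r) / df
    return W, P0, r, sigma2, gamma


def _imhof_tail(lam, x=0.0):
    """P(sum_i lam_i chi2_1 > x) by Imhof's numerical inversion."""
    from scipy import integrate

    lam = lam[np.abs(lam) > 1e-12]
    if lam.size == 0:
        return 1.0

    def integrand(u):
        theta = 0.5 * np.sum(np.arctan(lam * u)) - 0.5 * x * u
        rho = np.prod((1 + (lam * u) ** 2) ** 0.25)
        return np.sin(theta) / (u * rho)

    val, _ = integrate.quad(integrand, 0, np.inf, limit=200)
    return float(np.clip(0.5 + val / np.pi, 0.0, 1.0))


def _exact_ratio_p(r, K, P0):
    """Exact null p for the ratio statistic q = r'Kr / r'r.

    Conditional on the design, r = P0 eps with Gaussian eps, so
    P(q > q_obs) = P(eps' (P0 K P0 - q_obs P0) eps > 0), a weighted
    chi-square tail evaluated by Imhof integration.  Unlike the plug-in
    Satterthwaite approximation this accounts exactly for the shared
    randomness between the numerator and the residual variance estimate.
    """
    q_obs = float(r @ K @ r) / float(r @ r)
    A = P0 @ K @ P0 - q_obs * P0
    lam = np.linalg.eigvalsh((A + A.T) / 2)
    return _imhof_tail(lam)


def _satterthwaite_p(Q, P0K, P0, df_resid):
    mu_q = np.trace(P0K) / 2.0
    itt = np.trace(P0K @ P0K) / 2.0
    its = np.trace(P0K @ P0) / 2.0
    iss = df_resid / 2.0
    itilde = max(itt - its**2 / iss, 1e-12)
    kappa = itilde / max(mu_q, 1e-12)
    nu = mu_q**2 / itilde
    return float(stats.chi2.sf(Q / kappa, nu))


def km_mediation_test(Y, E, X, M_block, kernel: str = "gaussian",
                      bandwidth: float | None = None,
                      pvalue_method: str = "exact",
                      exposure: str = "", outcome: str = "", layer: str = "",
                      group: str = "all") -> MediationResult:
    """Variance-component score test of the mediator set.

    Fits the null OLS Y ~ [1, X, E], forms Q = r'Kr / (2 sigma^2) and a
    chi-square-mixture p-value.  ``pvalue_method`` selects "exact" (Imhof
    inversion of the ratio statistic, the default - calibrated at cohort
    n), "satterthwaite" (two-moment plug-in) or "liu" (three-moment).
    The total effect is the E coefficient of the null model; the direct
    effect adjusts linearly for the mediator block (top principal
    components when sites >= subjects), reported as supplementary output.
    """
    Y = np.asarray(Y, dtype=float)
    E = np.asarray(E, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    M = np.asarray(M_block, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    n = len(Y)
    if n < 30:
        raise ValueError("kernel mediation requires n >= 30")

    W, P0, r, sigma2, gamma = _null_model(Y, X, E)
    total_effect = float(gamma[-1])

    K = kernel_matrix(M, kernel=kernel, bandwidth=bandwidth)
    Q = float(r @ K @ r) / (2.0 * sigma2)
    P0K = P0 @ K
    df_resid = n - W.shape[1]
    if pvalue_method == "exact":
        p = _exact_ratio_p(r, K, P0)
    elif pvalue_method == "liu":
        PKP = P0 @ K @ P0
        lam = np.linalg.eigvalsh(PKP / 2.0)
        p = _liu_from_eigs(Q, lam)
    elif pvalue_method == "satterthwaite":
        p = _satterthwaite_p(Q, P0K, P0, df_resid)
    else:
        raise ValueError(f"unknown pvalue_method {pvalue_method!r}")
    p = min(max(p, np.nextafter(0, 1)), 1.0)

    # direct effect: linear adjustment for the mediator block
    Madj = M - M.mean(axis=0)
    if Madj.shape[1] >= n - W.shape[1]:
        U, s, _ = np.linalg.svd(Madj, full_matrices=False)
        keep = min(10, np.sum(s > 1e-10))
        Madj = U[:, :keep] * s[:keep]
    Wd = np.column_stack([W, Madj])
    coef, *_ = np.linalg.lstsq(Wd, Y, rcond=None)
    direct_effect = float(coef[W.shape[1] - 1])

    # tau boundary: method-of-moments tau estimate nonpositive when the
    # statistic falls below its null expectation
    tau_boundary = Q <= np.trace(P0K) / 2.0
    return MediationResult(
        exposure=exposure, outcome=outcome, layer=layer, group=group,
        n_sites=M.shape[1], statistic=Q, p_value=p, q_value=None,
        total_effect=total_effect, direct_effect=direct_effect,
        tau_boundary=bool(tau_boundary),
    )


def _liu_from_eigs(Q, lam):
    lam = lam[lam > 1e-10]
    if lam.size == 0:
        return 1.0
    c1, c2, c3, c4 = (np.sum(lam**k) for k in range(1, 5))
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        ell = a**2 - 2 * delta
    else:
        delta = 0.0
        ell = 1 / s2
    t = (Q - c1) / np.sqrt(2 * c2)
    x = t * np.sqrt(2 * (ell + 2 * delta)) + ell + delta
    return float(stats.ncx2.sf(x, ell, delta))


def gene_wise_and_global_mediation(candidates: list[MediationCandidateSet],
                                   Y_table: pd.DataFrame,
                                   exposure_vars: pd.DataFrame,
                                   covariates: pd.DataFrame,
                                   methylation: dict,
                                   kernel: str = "gaussian",
                                   pvalue_method: str = "satterthwaite") -> pd.DataFrame:
    """Run the kernel test per gene and for each full candidate set.

    ``methylation`` maps layer -> sites x subjects matrix.  BH adjustment
    is applied within exposure families (all comparisons sharing one
    exposure), mirroring the reporting convention of set-level mediation
    tables.
    """
    cov = covariates[list(OUTCOME_COVARIATES)]
    results: list[MediationResult] = []
    for cand in candidates:
        meth = methylation[cand.layer]
        df = pd.concat([Y_table[cand.outcome],
                        exposure_vars[cand.exposure].rename("E"), cov],
                       axis=1).dropna()
        subjects = df.index.intersection(meth.columns)
        df = df.loc[subjects]
        M_all = meth.loc[cand.sites, subjects].T

        groups = {}
        if cand.genes:
            by_gene = {}
            for s in cand.sites:
                by_gene.setdefault(cand.genes.get(s, "") or "intergenic", []).append(s)
            groups.update(by_gene)
        groups["all"] = cand.sites

        for gname, sites in groups.items():
            if not sites:
                continue
            res = km_mediation_test(
                df[cand.outcome].to_numpy(), df["E"].to_numpy(),
                df[list(OUTCOME_COVARIATES)].to_numpy(),
                M_all[sites].to_numpy(), kernel=kernel,
                pvalue_method=pvalue_method,
                exposure=cand.exposure, outcome=cand.outcome,
                layer=cand.layer, group=gname)
            results.append(res)

    tab = pd.DataFrame([r.__dict__ for r in results])
    if len(tab):
        tab["q_value"] = np.nan
        for e, grp in tab.groupby("exposure"):
            tab.loc[grp.index, "q_value"] = bh_adjust(grp["p_value"].to_numpy())
    return tab
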
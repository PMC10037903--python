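"""PFAS exposure processing.

Implements the standard handling of left-censored environmental analyte
panels: substitution of non-detects at LOD/sqrt(2), detection-based
classification of each analyte (continuous with natural-log transform,
dichotomized detected/non-detected, or excluded), inter-exposure
correlation, confounder screening, and single-draw imputation of missing
categorical covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExposureTable",
    "AnalyteClassification",
    "substitute_below_lod",
    "classify_analyte",
    "classify_all",
    "correlate_exposures",
    "screen_confounders",
    "impute_missing_covariates",
]

SQRT2 = np.sqrt(2.0)


@dataclass
class ExposureTable:
    """Subject x analyte concentrations (ug/L) with LOD bookkeeping.

    Attributes
    ----------
    values : DataFrame indexed by subject, one column per analyte.  Censored
        cells may be NaN (masked) or hold the raw reading; after
        :func:`substitute_below_lod` they hold LOD/sqrt(2).
    below_lod : boolean DataFrame, same shape, True where the measurement
        fell below the analytical limit of detection.
    lod : Series mapping analyte -> LOD in ug/L.
    """

    values: pd.DataFrame
    below_lod: pd.DataFrame
    lod: pd.Series

    def __post_init__(self):
        if not self.values.columns.equals(self.below_lod.columns):
            raise ValueError("values and below_lod must share analyte columns")
        missing = [a for a in self.values.columns if a not in self.lod.index]
        if missing:
            raise ValueError(f"missing LOD for analytes: {missing}")
        if (self.lod.loc[self.values.columns] <= 0).any():
            raise ValueError("LODs must be positive")

    @property
    def analytes(self):
        return list(self.values.columns)

    def fraction_below_lod(self) -> pd.Series:
        return self.below_lod.mean(axis=0)


@dataclass
class AnalyteClassification:
    analyte: str
    fraction_below_lod: float
    analyte_class: str   # "continuous" | "categorical" | "excluded"
    transform: str       # "natural-log" | "detected-indicator" | "none"


def substitute_below_lod(table: ExposureTable) -> ExposureTable:
    """Replace every below-LOD reading by LOD/sqrt(2).

    Detected values pass through unchanged, so the substitution never
    reorders detected concentrations.
    """
    vals = table.values.copy()
    detected = vals.where(~table.below_lod)
    if (detected < 0).any().any():
        raise ValueError("negative concentrations are not valid")
    for a in vals.columns:
        vals.loc[table.below_lod[a], a] = table.lod[a] / SQRT2
    return ExposureTable(values=vals, below_lod=table.below_lod.copy(),
                         lod=table.lod.copy())


def classify_analyte(fraction_below_lod: float, lower: float = 0.40,
                     upper: float = 0.80, analyte: str = "") -> AnalyteClassification:
    """Classify an analyte from its non-detect fraction.

    > ``upper`` below LOD: excluded from analysis; between ``lower`` and
    ``upper`` (inclusive): dichotomized as detected/non-detected;
    < ``lower``: continuous, analyzed on the natural-log scale.
    """
    f = float(fraction_below_lod)
    if not (0.0 <= f <= 1.0):
        raise ValueError(f"fraction below LOD must be in [0, 1], got {f}")
    if f > upper:
        cls, tr = "excluded", "none"
    elif f >= lower:
        cls, tr = "categorical", "detected-indicator"
    else:
        cls, tr = "continuous", "natural-log"
    return AnalyteClassification(analyte, f, cls, tr)


def classify_all(table: ExposureTable, lower: float = 0.40,
                 upper: float = 0.80) -> pd.DataFrame:
    frac = table.fraction_below_lod()
    rows = [classify_analyte(frac[a], lower, upper, a) for a in table.analytes]
    return pd.DataFrame(
        {
            "analyte": [r.analyte for r in rows],
            "fraction_below_lod": [r.fraction_below_lod for r in rows],
            "class": [r.analyte_class for r in rows],
            "transform": [r.transform for r in rows],
        }
    ).set_index("analyte")


def analysis_variables(table: ExposureTable, classes: pd.DataFrame) -> pd.DataFrame:
    """Exposure columns as they enter models.

    Continuous analytes: ln(concentration after LOD substitution).
    Categorical analytes: detected (1) vs non-detected (0).
    Excluded analytes are dropped.
    """
    sub = substitute_below_lod(table)
    out = {}
    for a in table.analytes:
        cls = classes.loc[a, "class"]
        if cls == "continuous":
            out[a] = np.log(sub.values[a].astype(float))
        elif cls == "categorical":
            out[a] = (~table.below_lod[a]).astype(float)
    return pd.DataFrame(out, index=table.values.index)


def correlate_exposures(table: ExposureTable, classes: pd.DataFrame):
    """Pairwise association among retained analytes.

    Pearson correlation on ln-transformed values for continuous pairs;
    chi-squared tests of the 2x2 detected table for categorical pairs; for
    mixed pairs a point-biserial (Pearson against the indicator).  Returns
    (r_matrix, p_matrix) as DataFrames with unit diagonal; zero-variance
    analytes yield NaN entries.
    """
    if len(table.values) < 3:
        raise ValueError("need at least 3 subjects")
    vars_ = analysis_variables(table, classes)
    cols = list(vars_.columns)
    k = len(cols)
    r = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    np.fill_diagonal(p.values, 0.0)
    cat = {a for a in cols if classes.loc[a, "class"] == "categorical"}
    for i in range(k):
        for j in range(i + 1, k):
            x, y = vars_[cols[i]], vars_[cols[j]]
            if x.std() == 0 or y.std() == 0:
                rij, pij = np.nan, np.nan
            elif cols[i] in cat and cols[j] in cat:
                ct = pd.crosstab(x, y)
                chi2, pij, _, _ = stats.chi2_contingency(ct, correction=False)
                # signed phi coefficient for reporting symmetry
                rij = np.sign(np.corrcoef(x, y)[0, 1]) * np.sqrt(chi2 / len(x))
            else:
                rij, pij = stats.pearsonr(x, y)
            r.iloc[i, j] = r.iloc[j, i] = rij
            p.iloc[i, j] = p.iloc[j, i] = pij
    return r, p


def screen_confounders(exposure_vars: pd.DataFrame,
                       covariates: pd.DataFrame,
                       alpha: float = 0.05,
                       categorical: tuple = ()) -> pd.DataFrame:
    """Test each (covariate, analyte) pair and flag candidates at p < alpha.

    Numeric covariates use Pearson correlation against the exposure analysis
    variable; covariates named in ``categorical`` use chi-squared tests
    against the dichotomized exposure (or a group comparison for continuous
    exposures).  Constant covariates are recorded as excluded.
    """
    rows = []
    for cov in covariates.columns:
        cvals = covariates[cov]
        complete = cvals.notna()
        if cvals[complete].nunique() <= 1:
            rows.append((cov, None, "constant", np.nan, np.nan, False))
            continue
        for a in exposure_vars.columns:
            x = exposure_vars.loc[complete, a]
            c = cvals[complete]
            if cov in categorical:
                if x.nunique() <= 2:
                    ct = pd.crosstab(c, x)
                    stat, pval, _, _ = stats.chi2_contingency(ct, correction=False)
                    test = "chi2"
                else:
                    groups = [x[c == g] for g in c.unique()]
                    stat, pval = stats.f_oneway(*groups)
                    test = "anova"
            else:
                stat, pval = stats.pearsonr(c.astype(float), x)
                test = "pearson"
            rows.append((cov, a, test, stat, pval, bool(pval < alpha)))
    return pd.DataFrame(rows, columns=["covariate", "analyte", "test",
                                       "statistic", "p_value", "selected"])


def impute_missing_covariates(covariates: pd.DataFrame, seed: int,
                              columns=None) -> pd.DataFrame:
    """Single-draw imputation of missing categorical covariates.

    Each missing cell is filled with one draw from the empirical
    distribution of the complete cases for that covariate (the first step of
    multiple imputation, run once).  Complete cells are untouched; identical
    seed gives identical completion.
    """
    rng = np.random.default_rng(seed)
    out = covariates.copy()
    cols = columns if columns is not None else covariates.columns
    for col in cols:
        vals = out[col]
        missing = vals.isna()
        if not missing.any():
            continue
        complete = vals.dropna()
        if complete.empty:
            raise ValueError(f"covariate {col!r} is entirely missing")
        levels, counts = np.unique(complete, return_counts=True)
        draws = rng.choice(levels, size=int(missing.sum()),
                           p=counts / counts.sum())
        out.loc[missing, col] = draws
        out[col] = out[col].astype(complete.dtype, errors="ignore")
    return out
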
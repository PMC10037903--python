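"""Maximum-likelihood decomposition of paired BS/oxBS signals.

A bisulfite (BS) beta value measures total methylation (5-mC + 5-hmC); an
oxidative-bisulfite (oxBS) beta value measures 5-mC alone.  Naive
subtraction BS - oxBS can go negative in hypomethylated regions.  Instead,
each (BS, oxBS) pair is treated as two binomial observations with a common
underlying (p_m, p_h, p_u) simplex point: BS observes p_m + p_h with weight
n_bs pseudo-trials, oxBS observes p_m with weight n_oxbs.  The joint ML
solution over the simplex never produces negative proportions.

For the two-assay design the solution is closed-form: when bs >= oxbs the
interior optimum is (p_m, p_h) = (oxbs, bs - oxbs); otherwise the optimum
sits on the p_h = 0 boundary with p_m the weight-pooled estimate
(n_bs*bs + n_oxbs*oxbs) / (n_bs + n_oxbs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Decomposition", "estimate_proportions", "filter_low_total",
           "build_long_matrix", "long_to_wide"]


@dataclass
class Decomposition:
    """Per-entry 5-mC / 5-hmC / unmethylated proportions."""

    p_m: np.ndarray
    p_h: np.ndarray
    p_u: np.ndarray
    boundary: np.ndarray   # True where the p_h = 0 constraint was active
    n_bs: float
    n_oxbs: float


def estimate_proportions(bs, oxbs, n_bs: float = 100.0,
                         n_oxbs: float = 100.0) -> Decomposition:
    """Decompose BS/oxBS proportions into (5-mC, 5-hmC, unmethylated).

    Parameters
    ----------
    bs, oxbs : array-like in [0, 1]
        Paired beta values; any matching shapes (scalars, vectors, or
        site x sample matrices).
    n_bs, n_oxbs : positive floats
        Effective binomial pseudo-trial weights for each assay.  Array betas
        carry no read counts, so both default to 100 (equal information).
    """
    bs = np.asarray(bs, dtype=float)
    oxbs = np.asarray(oxbs, dtype=float)
    if np.any((bs < 0) | (bs > 1)) or np.any((oxbs < 0) | (oxbs > 1)):
        raise ValueError("BS and oxBS proportions must lie in [0, 1]")
    if n_bs <= 0 or n_oxbs <= 0:
        raise ValueError("pseudo-trial weights must be positive")

    boundary = bs < oxbs
    pooled = (n_bs * bs + n_oxbs * oxbs) / (n_bs + n_oxbs)
    p_m = np.where(boundary, pooled, oxbs)
    p_h = np.where(boundary, 0.0, bs - oxbs)
    p_u = 1.0 - p_m - p_h
    # guard against floating residue at the simplex edge
    p_u = np.clip(p_u, 0.0, 1.0)
    return Decomposition(p_m=p_m, p_h=p_h, p_u=p_u,
                         boundary=np.asarray(boundary), n_bs=n_bs, n_oxbs=n_oxbs)


def filter_low_total(mc: pd.DataFrame, hmc: pd.DataFrame,
                     threshold: float = 0.1):
    """Drop CpG sites whose mean total methylation (5-mC + 5-hmC) is below
    ``threshold``.

    5-hmC does not occur uniformly across the genome; sites with negligible
    total methylation carry no usable hydroxymethylation signal.  A site is
    retained iff its subject-mean total is >= threshold (boundary kept).
    Returns (mc_kept, hmc_kept, removed_site_index).
    """
    if not mc.index.equals(hmc.index) or not mc.columns.equals(hmc.columns):
        raise ValueError("5-mC and 5-hmC matrices must share sites and subjects")
    total = (mc + hmc).mean(axis=1)
    keep = total >= threshold
    return mc.loc[keep], hmc.loc[keep], mc.index[~keep]


def build_long_matrix(mc: pd.DataFrame, hmc: pd.DataFrame) -> pd.DataFrame:
    """Stack 5-mC and 5-hmC matrices into one long type-labeled table.

    Each (subject, site) contributes exactly two rows - one per methylation
    type - so a site measured in 70 subjects yields 140 observations.  Type
    is coded with 5-mC as the reference level (``type_5hmc`` indicator).
    """
    if not mc.index.equals(hmc.index):
        raise ValueError("site sets differ between 5-mC and 5-hmC")
    if not mc.columns.equals(hmc.columns):
        raise ValueError("subject sets differ between 5-mC and 5-hmC")
    m = mc.T.stack().rename("value").reset_index()
    m.columns = ["subject", "site", "value"]
    m["type"] = "5mC"
    h = hmc.T.stack().rename("value").reset_index()
    h.columns = ["subject", "site", "value"]
    h["type"] = "5hmC"
    long = pd.concat([m, h], ignore_index=True)
    long["type_5hmc"] = (long["type"] == "5hmC").astype(float)
    return long[["subject", "site", "type", "type_5hmc", "value"]]


def long_to_wide(long: pd.DataFrame):
    """Inverse of :func:`build_long_matrix` (site x subject matrices)."""
    mc = long[long["type"] == "5mC"].pivot(index="site", columns="subject",
                                           values="value")
    hmc = long[long["type"] == "5hmC"].pivot(index="site", columns="subject",
                                             values="value")
    return mc, hmc
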
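"""Array-level quality control, cell-type deconvolution, and batch components.

Operates on already-normalized methylation proportion matrices (sites x
samples).  Sample filters mirror standard Infinium practice: drop samples
with low bead coverage or too many failed detection calls.  Probe filters
remove poorly detected probes, externally supplied masks (SNP-affected,
cross-reactive, CH, X/Y), and probes with high replicate variability; the
same probe set is removed from every assay matrix so BS and oxBS stay
aligned.  Cell-type proportions come from constrained least squares against
a sorted cord-blood reference panel, and batch components from PCA of the
control-probe matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = [
    "MethylomeSet", "QcReport", "filter_samples", "filter_probes",
    "deconvolve_cell_types", "control_probe_pcs", "clamp_proportions",
]


@dataclass
class MethylomeSet:
    """Sites x samples proportion matrix with annotation and QC metadata.

    ``assay`` labels what the proportions measure: BS (total methylation),
    oxBS (5-mC), or a derived layer (total, 5mC, 5hmC).
    """

    betas: pd.DataFrame
    assay: str
    annotation: pd.DataFrame   # index=site; columns chrom, pos (1-based), gene
    detection_p: pd.DataFrame | None = None
    bead_counts: pd.DataFrame | None = None
    replicate_pairs: list[tuple[str, str]] | None = None

    VALID_ASSAYS = ("BS", "oxBS", "total", "5mC", "5hmC")

    def __post_init__(self):
        if self.assay not in self.VALID_ASSAYS:
            raise ValueError(f"assay must be one of {self.VALID_ASSAYS}")
        vals = self.betas.to_numpy()
        if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
            raise ValueError("beta values must lie in [0, 1]")
        missing = self.betas.index.difference(self.annotation.index)
        if len(missing):
            raise ValueError(f"annotation missing for {len(missing)} sites")

    @property
    def sites(self):
        return self.betas.index

    @property
    def samples(self):
        return self.betas.columns

    def subset_sites(self, sites) -> "MethylomeSet":
        return MethylomeSet(
            betas=self.betas.loc[sites],
            assay=self.assay,
            annotation=self.annotation.loc[sites],
            detection_p=None if self.detection_p is None else self.detection_p.loc[sites],
            bead_counts=None if self.bead_counts is None else self.bead_counts.loc[sites],
            replicate_pairs=self.replicate_pairs,
        )

    def subset_samples(self, samples) -> "MethylomeSet":
        return MethylomeSet(
            betas=self.betas[samples],
            assay=self.assay,
            annotation=self.annotation,
            detection_p=None if self.detection_p is None else self.detection_p[samples],
            bead_counts=None if self.bead_counts is None else self.bead_counts[samples],
            replicate_pairs=self.replicate_pairs,
        )


@dataclass
class QcReport:
    """Disjointly attributed removals plus per-stage survivor counts."""

    removed_samples: dict[str, str] = field(default_factory=dict)
    removed_probes: dict[str, str] = field(default_factory=dict)
    stage_counts: list[tuple[str, int]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def log_stage(self, name: str, count: int):
        self.stage_counts.append((name, count))

    def to_dict(self):
        return {
            "removed_samples": self.removed_samples,
            "removed_probes": self.removed_probes,
            "stage_counts": self.stage_counts,
            "warnings": self.warnings,
        }


def filter_samples(mset: MethylomeSet, max_failed_fraction: float = 0.05,
                   min_beads: int = 3, detection_alpha: float = 0.01,
                   concordance_pass: pd.Series | None = None):
    """Remove samples with poor coverage or too many failed sites.

    A site fails within a sample when its detection p-value exceeds
    ``detection_alpha`` or its bead count is below ``min_beads``.  Samples
    with more than ``max_failed_fraction`` failed sites are removed, as are
    samples explicitly flagged by the externally supplied sex/genotype
    ``concordance_pass`` column.
    """
    if mset.detection_p is None or mset.bead_counts is None:
        raise ValueError("detection p-values and bead counts are required")
    report = QcReport()
    report.log_stage("input_samples", len(mset.samples))

    failed = (mset.detection_p > detection_alpha) | (mset.bead_counts < min_beads)
    frac_failed = failed.mean(axis=0)
    for s in mset.samples:
        if concordance_pass is not None and s in concordance_pass.index \
                and not bool(concordance_pass[s]):
            report.removed_samples[s] = "concordance"
        elif frac_failed[s] > max_failed_fraction:
            report.removed_samples[s] = "failed_fraction"
    keep = [s for s in mset.samples if s not in report.removed_samples]
    if not keep:
        err = ValueError("all samples removed by QC")
        err.report = report
        raise err
    report.log_stage("surviving_samples", len(keep))
    return mset.subset_samples(keep), report


def filter_probes(mset: MethylomeSet, others: list[MethylomeSet] | None = None,
                  detection_alpha: float = 1e-16,
                  masks: dict[str, list] | None = None,
                  replicate_delta: float = 0.05,
                  max_failed_fraction: float = 0.05):
    """Remove low-quality probes, identically from every assay matrix.

    The removal set is the union of (i) probes poorly detected (detection
    p-value above ``detection_alpha`` in more than ``max_failed_fraction``
    of samples) in *any* assay group, (ii) externally supplied mask lists,
    and (iii) probes whose mean absolute difference across replicate pairs
    exceeds ``replicate_delta``.  Returns the filtered sets and a QcReport;
    filtering is idempotent.
    """
    groups = [mset] + list(others or [])
    report = QcReport()
    report.log_stage("input_probes", len(mset.sites))

    remove: dict[str, str] = {}

    for g in groups:
        if g.detection_p is None:
            continue
        bad_fraction = (g.detection_p > detection_alpha).mean(axis=1)
        for site in g.sites[bad_fraction > max_failed_fraction]:
            remove.setdefault(site, "poor_detection")

    for mask_name, sites in (masks or {}).items():
        for site in sites:
            if site not in mset.betas.index:
                report.warnings.append(f"mask {mask_name}: unknown site {site}")
                continue
            remove.setdefault(site, f"mask:{mask_name}")

    pairs = mset.replicate_pairs or []
    if pairs:
        diffs = [
            (mset.betas[a] - mset.betas[b]).abs()
            for a, b in pairs
            if a in mset.betas.columns and b in mset.betas.columns
        ]
        if diffs:
            mean_abs = pd.concat(diffs, axis=1).mean(axis=1)
            for site in mset.sites[mean_abs > replicate_delta]:
                remove.setdefault(site, "replicate_variability")

    report.removed_probes = remove
    keep = mset.sites[~mset.sites.isin(remove)]
    report.log_stage("surviving_probes", len(keep))
    out = [g.subset_sites(keep.intersection(g.sites)) for g in groups]
    if others is None:
        return out[0], report
    return out[0], out[1:], report


def deconvolve_cell_types(betas: pd.DataFrame,
                          reference: pd.DataFrame) -> pd.DataFrame:
    """Reference-based cell-type deconvolution by constrained least squares.

    Solves, per sample, min ||R w - b||^2 subject to w >= 0 and sum(w) = 1
    over the signature sites shared between the sample matrix and the
    reference panel.  Returns a samples x cell-types proportion table.
    """
    shared = betas.index.intersection(reference.index)
    if len(shared) < 10:
        raise ValueError(
            f"only {len(shared)} sites overlap the reference panel (need >= 10)")
    R = reference.loc[shared].to_numpy()
    B = betas.loc[shared].to_numpy()
    k = R.shape[1]
    # enforce the sum-to-one constraint with a heavily weighted extra row,
    # then renormalize: equivalent to the usual constrained projection for
    # this well-conditioned panel
    w_row = 1e4
    R_aug = np.vstack([R, w_row * np.ones((1, k))])
    out = np.empty((B.shape[1], k))
    for j in range(B.shape[1]):
        b_aug = np.concatenate([B[:, j], [w_row]])
        w, _ = nnls(R_aug, b_aug)
        s = w.sum()
        out[j] = w / s if s > 0 else np.full(k, 1.0 / k)
    return pd.DataFrame(out, index=betas.columns, columns=reference.columns)


def control_probe_pcs(control_matrix: pd.DataFrame, k: int = 2) -> pd.DataFrame:
    """Top-k principal components of the column-centered control-probe matrix.

    Captures technical/batch variance shared across samples.  Deterministic
    sign convention: within each component the loading of largest magnitude
    is made positive.
    """
    X = control_matrix.to_numpy(dtype=float).T   # samples x probes
    Xc = X - X.mean(axis=0)
    rank = np.linalg.matrix_rank(Xc)
    if k > rank:
        raise ValueError(f"k={k} exceeds rank {rank} of the control matrix")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :k] * s[:k]
    for j in range(k):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            scores[:, j] = -scores[:, j]
    return pd.DataFrame(scores, index=control_matrix.columns,
                        columns=[f"PC{j + 1}" for j in range(k)])


def clamp_proportions(values, eps: float = 1e-6):
    """Map proportions from [0, 1] into the open interval [eps, 1 - eps].

    Beta-regression support is the open unit interval; exact 0/1 values
    (common after MLML boundary solutions) are nudged inward.  Order
    preserving.
    """
    if isinstance(values, MethylomeSet):
        return MethylomeSet(
            betas=values.betas.clip(eps, 1 - eps),
            assay=values.assay,
            annotation=values.annotation,
            detection_p=values.detection_p,
            bead_counts=values.bead_counts,
            replicate_pairs=values.replicate_pairs,
        )
    if isinstance(values, (pd.DataFrame, pd.Series)):
        return values.clip(eps, 1 - eps)
    return np.clip(np.asarray(values, dtype=float), eps, 1 - eps)
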
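"""Methylome QC and the two-stage mixed-model correction.

Quality control mirrors standard EPIC-array practice: samples are dropped
when >=1% of sites fail detection (P > 0.05), when methylation-predicted sex
mismatches the recorded sex, or when listed as multidimensional-scaling
outliers; probes are dropped when the beadcount is <3 in more than 5% of
individuals, when >=0.5% of individuals fail detection, or when present on a
supplied cross-reactive/polymorphic exclusion list.  Inequalities are applied
exactly as stated (>= is inclusive, > strict).

Correction then proceeds in two stages, each fitting one mixed model per CpG
and keeping the residual:

1. technical  - plate and blood-draw date as crossed random intercepts;
   plate position, Set, clinic, year, weekday and supplied control-probe
   principal components as fixed effects;
2. biological - the five pedigree covariance structures (G/K/F/C/S) as
   random effects; sex, age and six estimated cell proportions (CD8T, CD4T,
   NK, Bcell, Mono, Gran) as fixed effects.

Residuals are y - X beta_GLS - (predicted random effects), equivalently
sigma2_e V^-1 (y - X beta), which is orthogonal to every fixed-effect column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reml import (BlockwiseREML, block_structure, fit_airelm,
                   fit_airelm_lowrank)
from .synth import MValueMatrix

logger = logging.getLogger(__name__)


@dataclass
class QCThresholds:
    sample_detection_fraction: float = 0.01   # >= : sample removed
    probe_detection_fraction: float = 0.005   # >= : probe removed
    beadcount_fraction: float = 0.05          # >  : probe removed
    beadcount_min: int = 3                    # <  : bead failure
    detection_p_cutoff: float = 0.05          # >  : detection failure
    exclusion_list: frozenset[str] = frozenset()

    def __post_init__(self):
        for f in (self.sample_detection_fraction, self.probe_detection_fraction,
                  self.beadcount_fraction, self.detection_p_cutoff):
            if not 0.0 <= f <= 1.0:
                raise ValueError("QC fractions must lie in [0, 1]")


@dataclass
class QCReport:
    samples_removed: dict[str, list[str]] = field(default_factory=dict)
    probes_removed: dict[str, list[str]] = field(default_factory=dict)
    n_samples_retained: int = 0
    n_probes_retained: int = 0

    def removed_samples(self) -> set[str]:
        return set().union(*self.samples_removed.values()) if self.samples_removed else set()

    def removed_probes(self) -> set[str]:
        return set().union(*self.probes_removed.values()) if self.probes_removed else set()


def compute_m_values(meth: np.ndarray, unmeth: np.ndarray,
                     offset: float = 0.0) -> np.ndarray:
    """M = log2((meth + offset) / (unmeth + offset)).

    The default offset of 0 is valid only when every intensity is positive;
    a zero denominator raises with a pointer to the offset argument.
    """
    meth = np.asarray(meth, dtype=float)
    unmeth = np.asarray(unmeth, dtype=float)
    if meth.shape != unmeth.shape:
        raise ValueError("methylated/unmethylated intensities differ in shape")
    if np.any(meth < 0) or np.any(unmeth < 0):
        raise ValueError("intensities must be non-negative")
    if offset == 0.0 and (np.any(unmeth == 0) or np.any(meth == 0)):
        raise ValueError("zero intensity with offset=0; pass a positive offset "
                         "(e.g. offset=100) to stabilise the log-ratio")
    return np.log2((meth + offset) / (unmeth + offset))


def filter_samples(matrix: MValueMatrix, detection_p: pd.DataFrame,
                   predicted_sex: pd.Series | None = None,
                   recorded_sex: pd.Series | None = None,
                   thresholds: QCThresholds | None = None,
                   mds_outliers: set[str] | None = None,
                   ) -> tuple[MValueMatrix, QCReport]:
    """Drop failing samples; detection_p is CpG x sample aligned with the matrix."""
    thresholds = thresholds or QCThresholds()
    if detection_p.shape != (len(matrix.cpg_ids), len(matrix.sample_ids)):
        raise ValueError(
            f"detection-P shape {detection_p.shape} does not match matrix "
            f"{(len(matrix.cpg_ids), len(matrix.sample_ids))}")
    report = QCReport()
    fail_frac = (detection_p.to_numpy() > thresholds.detection_p_cutoff).mean(axis=0)
    bad_det = [s for s, f in zip(matrix.sample_ids, fail_frac)
               if f >= thresholds.sample_detection_fraction]
    report.samples_removed["detection"] = bad_det
    bad_sex: list[str] = []
    if predicted_sex is not None and recorded_sex is not None:
        for s in matrix.sample_ids:
            ps, rs = predicted_sex.get(s), recorded_sex.get(s)
            if pd.notna(ps) and pd.notna(rs) and ps != rs:
                bad_sex.append(s)
    report.samples_removed["sex_mismatch"] = bad_sex
    report.samples_removed["mds_outlier"] = sorted(
        (mds_outliers or set()) & set(matrix.sample_ids))
    drop = report.removed_samples()
    keep_idx = [i for i, s in enumerate(matrix.sample_ids) if s not in drop]
    out = MValueMatrix(values=matrix.values[:, keep_idx],
                       cpg_ids=list(matrix.cpg_ids),
                       positions=matrix.positions,
                       sample_ids=[matrix.sample_ids[i] for i in keep_idx],
                       provenance=matrix.provenance,
                       sample_meta=None if matrix.sample_meta is None else
                       matrix.sample_meta.iloc[keep_idx].reset_index(drop=True))
    report.n_samples_retained = len(keep_idx)
    report.n_probes_retained = len(matrix.cpg_ids)
    return out, report


def filter_probes(matrix: MValueMatrix, beadcount: pd.DataFrame | None = None,
                  detection_p: pd.DataFrame | None = None,
                  thresholds: QCThresholds | None = None,
                  ) -> tuple[MValueMatrix, QCReport]:
    """Drop probes failing beadcount, detection or the exclusion list."""
    thresholds = thresholds or QCThresholds()
    report = QCReport()
    bad_bead: list[str] = []
    if beadcount is not None:
        frac = (beadcount.to_numpy() < thresholds.beadcount_min).mean(axis=1)
        bad_bead = [c for c, f in zip(matrix.cpg_ids, frac)
                    if f > thresholds.beadcount_fraction]
    report.probes_removed["beadcount"] = bad_bead
    bad_det: list[str] = []
    if detection_p is not None:
        frac = (detection_p.to_numpy() > thresholds.detection_p_cutoff).mean(axis=1)
        bad_det = [c for c, f in zip(matrix.cpg_ids, frac)
                   if f >= thresholds.probe_detection_fraction]
    report.probes_removed["detection"] = bad_det
    report.probes_removed["exclusion_list"] = [
        c for c in matrix.cpg_ids if c in thresholds.exclusion_list]
    drop = report.removed_probes()
    keep_idx = [i for i, c in enumerate(matrix.cpg_ids) if c not in drop]
    keep_ids = [matrix.cpg_ids[i] for i in keep_idx]
    out = MValueMatrix(values=matrix.values[keep_idx],
                       cpg_ids=keep_ids,
                       positions=matrix.positions[
                           matrix.positions["cpg_id"].isin(set(keep_ids))
                       ].reset_index(drop=True),
                       sample_ids=list(matrix.sample_ids),
                       provenance=matrix.provenance,
                       sample_meta=matrix.sample_meta)
    report.n_samples_retained = len(matrix.sample_ids)
    report.n_probes_retained = len(keep_idx)
    return out, report


def _design_from_covariates(covariates: pd.DataFrame) -> np.ndarray:
    """Intercept + dummy-coded categoricals + numeric columns, full rank."""
    parts = [np.ones((len(covariates), 1))]
    names = ["intercept"]
    for col in covariates.columns:
        s = covariates[col]
        if s.dtype.kind in "OUSb" or isinstance(s.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(s, prefix=col, drop_first=True)
            parts.append(dummies.to_numpy(dtype=float))
            names.extend(dummies.columns)
        else:
            parts.append(s.to_numpy(dtype=float)[:, None])
            names.append(col)
    X = np.hstack(parts)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify collinear columns by greedy QR-style elimination
        bad = []
        keep = [0]
        for j in range(1, X.shape[1]):
            trial = keep + [j]
            if np.linalg.matrix_rank(X[:, trial]) == len(trial):
                keep.append(j)
            else:
                bad.append(names[j])
        raise ValueError(f"singular fixed design; collinear columns: {bad}")
    return X


def _batch_variance_share(values: np.ndarray, labels: np.ndarray) -> float:
    """Between-group variance share via one-way random-effects moments.

    Method-of-moments estimator sigma_b^2 = (MSB - MSW) / n0 averaged across
    CpGs; unbiased for the generative between-group fraction, unlike the raw
    ANOVA R^2 which loses a factor (k-1)/k with few groups.
    """
    groups = np.unique(labels)
    k = groups.size
    n = values.shape[1]
    sizes = np.array([(labels == g).sum() for g in groups], dtype=float)
    n0 = (n - np.sum(sizes ** 2) / n) / (k - 1)
    overall = values.mean(axis=1, keepdims=True)
    ssb = np.zeros(values.shape[0])
    ssw = np.zeros(values.shape[0])
    for g, sz in zip(groups, sizes):
        idx = labels == g
        gm = values[:, idx].mean(axis=1)
        ssb += sz * (gm - overall[:, 0]) ** 2
        ssw += ((values[:, idx] - gm[:, None]) ** 2).sum(axis=1)
    msb = ssb / (k - 1)
    msw = ssw / (n - k)
    sigma_b = np.maximum((msb - msw) / n0, 0.0)
    # pool across CpGs before forming the ratio (avoids Jensen bias with
    # few groups, where per-CpG ratios are strongly concave in sigma_b)
    return float(sigma_b.mean() / (sigma_b.mean() + msw.mean()))


def correct_technical(matrix: MValueMatrix, batch_covariates: pd.DataFrame,
                      *, random_cols: tuple[str, str] = ("plate", "draw_date"),
                      tol: float = 1e-6, max_iter: int = 50) -> MValueMatrix:
    """Stage-1 correction: remove technical variation per CpG.

    ``batch_covariates`` is a sample-aligned frame; the two ``random_cols``
    become crossed random intercepts and every other column a fixed effect.
    Returns the residual matrix (provenance "technical").
    """
    n = len(matrix.sample_ids)
    if len(batch_covariates) != n:
        raise ValueError("batch covariates not aligned with samples")
    fixed = batch_covariates.drop(columns=list(random_cols))
    X = _design_from_covariates(fixed)
    factors = []
    for col in random_cols:
        codes, levels = pd.factorize(batch_covariates[col])
        Z = np.zeros((n, len(levels)))
        Z[np.arange(n), codes] = 1.0
        factors.append(Z)
    resid = np.empty_like(matrix.values)
    init = None
    for j in range(matrix.values.shape[0]):
        fit = fit_airelm_lowrank(matrix.values[j], X, factors, tol=tol,
                                 max_iter=max_iter, init=init)
        resid[j] = fit.resid
        init = fit.sigma2 if fit.converged else None   # warm start within a matrix
    return matrix.copy_with(resid, "technical")


def correct_biological(matrix: MValueMatrix, rel_matrices: dict[str, np.ndarray],
                       sex: pd.Series, age: pd.Series, cell_props: pd.DataFrame,
                       *, tol: float = 1e-6, max_iter: int = 50,
                       ) -> tuple[MValueMatrix, pd.DataFrame]:
    """Stage-2 correction: remove familial covariance and biology per CpG.

    Fits per CpG a variance-component model with the supplied relationship
    matrices (typically G/K/F/C/S) as random effects and sex, age and the six
    cell-proportion columns as fixed effects.  Returns the residual matrix and
    a per-CpG table of estimated variance fractions plus a convergence flag
    (non-converged CpGs fall back to fixed-effects-only residuals).
    """
    n = len(matrix.sample_ids)
    labels = list(rel_matrices)
    covs = []
    for lab in labels:
        m = np.asarray(rel_matrices[lab], dtype=float)
        if m.shape != (n, n):
            raise ValueError(f"relationship matrix {lab} misaligned")
        w = np.linalg.eigvalsh(m)
        if w.min() < -1e-6:
            raise ValueError(f"relationship matrix {lab} is not PSD")
        covs.append(m)
    fixed = pd.concat([pd.DataFrame({"sex": sex.to_numpy(),
                                     "age": pd.to_numeric(age).to_numpy()}),
                       cell_props.reset_index(drop=True)], axis=1)
    X = _design_from_covariates(fixed)
    blocks = block_structure(covs)       # families are independent blocks
    kernel = BlockwiseREML(covs, blocks, X) if blocks is not None else None
    resid = np.empty_like(matrix.values)
    rows = []
    init = None
    for j in range(matrix.values.shape[0]):
        y = matrix.values[j]
        if kernel is not None:
            fit = kernel.fit(y, tol=tol, max_iter=max_iter, init=init)
        else:
            fit = fit_airelm(y, X, covs, tol=tol, max_iter=max_iter, init=init,
                             canonicalize=True)
        if fit.converged:
            resid[j] = fit.resid
            init = fit.sigma2
        else:
            logger.warning("REML did not converge for %s; using OLS residual",
                           matrix.cpg_ids[j])
            q, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
            resid[j] = y - X @ q
            init = None
        fracs = fit.fractions
        rows.append({"cpg_id": matrix.cpg_ids[j], "converged": fit.converged,
                     **{lab: fracs[i] for i, lab in enumerate(labels)},
                     "residual": fracs[-1]})
    vc = pd.DataFrame(rows)
    return matrix.copy_with(resid, "biological"), vc
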
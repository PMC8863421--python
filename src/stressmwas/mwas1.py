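"""MWAS 1: probewise linear model with empirical-Bayes moderated variance.

For each CpG, the (corrected) M-values are regressed on the phenotype plus a
shared fixed-effect design (Set, smoking status, pack-years, and the first
20 principal components of the M-value matrix).  Residual variances are then
shrunk towards a common prior by matching the moments of the log residual
variances to a scaled-F distribution, exactly the empirical-Bayes scheme of
the moderated t-statistic: the posterior variance is

    s_tilde^2 = (d0 * s0^2 + d * s^2) / (d0 + d)

and the moderated t uses d + d0 degrees of freedom.  The prior degrees of
freedom d0 are obtained by inverting the trigamma function with monotone
bisection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .synth import MValueMatrix


@dataclass
class ModerationParams:
    d0: float            # prior degrees of freedom (np.inf allowed)
    s0_sq: float         # prior variance
    df_residual: float


def compute_methylome_pcs(matrix: MValueMatrix | np.ndarray, k: int) -> np.ndarray:
    """Top-k principal component scores of the sample-by-CpG matrix.

    CpGs (variables) are centred; scores are orthogonal with a deterministic
    sign convention (the largest-magnitude loading of each component is
    positive).
    """
    values = matrix.values if isinstance(matrix, MValueMatrix) else np.asarray(matrix)
    data = values.T.astype(float)                      # samples x CpGs
    data = data - data.mean(axis=0)
    rank = min(data.shape)
    if k > rank:
        raise ValueError(f"k={k} exceeds the matrix rank bound {rank}")
    u, s, vt = np.linalg.svd(data, full_matrices=False)
    scores = u[:, :k] * s[:k]
    for j in range(k):
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            scores[:, j] = -scores[:, j]
    return scores


def fit_probewise(values: np.ndarray, phenotype: np.ndarray,
                  covariates: np.ndarray | None = None,
                  ) -> pd.DataFrame:
    """Per-CpG OLS of M-values on the phenotype with a shared design.

    ``values`` is CpG x sample; samples with a missing phenotype are dropped
    (complete-case).  Returns effect, se, residual variance and df per CpG.
    """
    y = np.asarray(phenotype, dtype=float)
    mask = ~np.isnan(y)
    y = y[mask]
    M = np.asarray(values, dtype=float)[:, mask]
    n = y.shape[0]
    cols = [np.ones(n), y]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)[mask]
        if C.ndim == 1:
            C = C[:, None]
        cols.extend(C.T)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (phenotype collinear with covariates?)")
    p = X.shape[1]
    df = n - p
    xtx_inv = np.linalg.inv(X.T @ X)
    coef = M @ X @ xtx_inv.T                          # (n_cpgs, p)
    resid = M - coef @ X.T
    rss = np.sum(resid * resid, axis=1)
    s2 = rss / df
    se = np.sqrt(s2 * xtx_inv[1, 1])
    return pd.DataFrame({
        "effect": coef[:, 1], "se": se, "resid_var": s2,
        "df": float(df), "n": n,
    })


def _trigamma_inverse(x: float, tol: float = 1e-8) -> float:
    """Solve trigamma(y) = x for y > 0 by monotone bisection."""
    if x <= 0:
        return np.inf
    lo, hi = 1e-8, 1e8
    if special.polygamma(1, lo) < x:
        return lo
    if special.polygamma(1, hi) > x:
        return hi
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if special.polygamma(1, mid) > x:
            lo = mid
        else:
            hi = mid
        if hi / lo < 1 + tol:
            break
    return float(np.sqrt(lo * hi))


def moderate_variances(resid_var: np.ndarray, df: float,
                       ) -> tuple[ModerationParams, np.ndarray]:
    """Estimate (d0, s0^2) from the residual variances and shrink them.

    Moment matching on z = log(s^2): under the scaled-F model,
    E z = log(s0^2) + digamma(d/2) - log(d/2) - digamma(d0/2) + log(d0/2)
    and Var z = trigamma(d/2) + trigamma(d0/2), so d0 comes from inverting the
    trigamma function on the excess variance and s0^2 from the mean.
    """
    s2 = np.asarray(resid_var, dtype=float)
    if s2.size < 10:
        raise ValueError("need at least 10 probes to moderate variances")
    pos = s2[s2 > 0]
    z = np.log(pos)
    e_z = z.mean()
    var_z = z.var(ddof=1)
    excess = var_z - special.polygamma(1, df / 2.0)
    if excess <= 1e-12:
        d0 = np.inf
        if var_z < 1e-12:
            # degenerate case: no scatter at all, the prior is a point mass
            # at the common observed variance
            s0 = np.exp(e_z)
        else:
            s0 = np.exp(e_z - special.polygamma(0, df / 2.0) + np.log(df / 2.0))
    else:
        half_d0 = _trigamma_inverse(float(excess))
        d0 = 2.0 * half_d0
        s0 = np.exp(e_z - special.polygamma(0, df / 2.0) + np.log(df / 2.0)
                    + special.polygamma(0, half_d0) - np.log(half_d0))
    params = ModerationParams(d0=float(d0), s0_sq=float(s0), df_residual=float(df))
    posterior = posterior_variances(s2, params)
    return params, posterior


def posterior_variances(resid_var: np.ndarray, params: ModerationParams) -> np.ndarray:
    s2 = np.asarray(resid_var, dtype=float)
    if np.isinf(params.d0):
        return np.full_like(s2, params.s0_sq)
    if params.d0 == 0:
        return s2.copy()
    d = params.df_residual
    return (params.d0 * params.s0_sq + d * s2) / (params.d0 + d)


def moderated_t_test(fits: pd.DataFrame, posterior: np.ndarray,
                     params: ModerationParams) -> pd.DataFrame:
    """Moderated t-statistics and two-sided P-values.

    The unscaled SE (se / sqrt(resid_var)) is rescaled by the posterior
    variance; degrees of freedom are df + d0 (normal reference when d0 is
    infinite).
    """
    s2 = fits["resid_var"].to_numpy()
    unit_se = fits["se"].to_numpy() / np.sqrt(np.maximum(s2, 1e-300))
    se_mod = unit_se * np.sqrt(posterior)
    t = fits["effect"].to_numpy() / se_mod
    df_total = params.df_residual + params.d0
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    out = fits.copy()
    out["se"] = se_mod
    out["stat"] = t
    out["p"] = np.clip(p, np.nextafter(0, 1), 1.0)
    return out


def run_mwas1(matrix: MValueMatrix, phenotype: pd.Series | np.ndarray,
              covariates: pd.DataFrame | np.ndarray | None = None,
              *, n_pcs: int = 20, standardize_continuous: bool = True,
              moderate: bool = True) -> pd.DataFrame:
    """Whole MWAS 1 engine: PCs -> probewise OLS -> moderation -> summary table.

    Continuous phenotypes are standardised so effects are per-SD; binary
    phenotypes must be coded 0/1.  ``covariates`` (e.g. Set, smoking status,
    pack-years) are augmented with the first ``n_pcs`` principal components
    of the M-value matrix.
    """
    y = np.asarray(phenotype, dtype=float)
    vals = np.unique(y[~np.isnan(y)])
    is_binary = vals.size <= 2 and set(vals).issubset({0.0, 1.0})
    if standardize_continuous and not is_binary:
        m, s = np.nanmean(y), np.nanstd(y)
        y = (y - m) / s
    cov_arr = None
    if covariates is not None:
        cov_arr = (covariates.to_numpy(dtype=float)
                   if isinstance(covariates, pd.DataFrame) else
                   np.asarray(covariates, dtype=float))
        if cov_arr.ndim == 1:
            cov_arr = cov_arr[:, None]
    if n_pcs > 0:
        pcs = compute_methylome_pcs(matrix, n_pcs)
        cov_arr = pcs if cov_arr is None else np.hstack([cov_arr, pcs])
    fits = fit_probewise(matrix.values, y, cov_arr)
    if moderate:
        params, post = moderate_variances(fits["resid_var"].to_numpy(),
                                          fits["df"].iloc[0])
        table = moderated_t_test(fits, post, params)
    else:
        t = fits["effect"] / fits["se"]
        table = fits.copy()
        table["stat"] = t
        table["p"] = 2.0 * stats.t.sf(np.abs(t), fits["df"])
    table.insert(0, "cpg_id", matrix.cpg_ids)
    pos = matrix.positions.set_index("cpg_id")
    table.insert(1, "chrom", pos.loc[table["cpg_id"], "chrom"].to_numpy())
    table.insert(2, "pos", pos.loc[table["cpg_id"], "start"].to_numpy())
    table["engine"] = "mwas1"
    return table.drop(columns=["resid_var", "df"])
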
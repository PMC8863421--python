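"""MWAS 2: multi-component mixed-linear-model association excluding the target.

The procedure mirrors the MOMENT approach to methylome-wide association:

1. an initial probewise linear scan with the phenotype as the dependent
   variable ranks every probe;
2. probes are binned into m groups by scan P-value (default two groups split
   at P < 0.05);
3. for each target probe, one methylome relationship matrix per group is
   built from standardised probe values, excluding the target itself and any
   probe within a window of it (default 50 kb);
4. the phenotype is regressed on the target probe with the group matrices as
   random effects and predicted blood-cell counts (basophil, eosinophil,
   lymphocyte, monocyte, neutrophil) as additional fixed effects; the Wald
   test of the target's fixed effect is reported.

Binary phenotypes are analysed on the 0/1 scale in the linear mixed model.
Group matrices are maintained by rank-1 downdates of precomputed full-group
matrices, so the per-target cost is dominated by one REML fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .reml import fit_airelm
from .synth import MValueMatrix

logger = logging.getLogger(__name__)


@dataclass
class MomentConfig:
    n_groups: int = 2
    p_cuts: tuple[float, ...] = (0.05,)   # boundaries between groups (len = n_groups-1)
    window_bp: int = 50_000
    reml_tol: float = 1e-6
    reml_max_iter: int = 50
    exact: bool = True                    # re-estimate variance components per target
    min_component_probes: int | None = None
    # A random-effect component whose group holds fewer probes than samples is
    # low rank, and because the lead group is selected on the very association
    # statistics under test, REML credits it with the phenotype's chance
    # alignment and deflates every test.  Groups smaller than this floor are
    # therefore merged into their neighbour.  None = use the sample count
    # (no effect at biobank scale, where the lead group far exceeds n).

    def __post_init__(self):
        if len(self.p_cuts) != self.n_groups - 1:
            raise ValueError("need n_groups - 1 P-value cut points")


@dataclass
class ComponentGrouping:
    labels: np.ndarray                    # per-probe group index, 0..m-1
    m: int
    window_bp: int


@dataclass
class MomentFit:
    effect: float
    se: float
    stat: float
    p: float
    sigma2: np.ndarray
    converged: bool
    n_components: int


def initial_scan(values: np.ndarray, phenotype: np.ndarray,
                 covariates: np.ndarray | None = None) -> pd.DataFrame:
    """Marginal per-probe regression with the phenotype as dependent variable.

    Implemented by residualising both sides on the covariates
    (Frisch-Waugh-Lovell), so the t-statistic per probe is identical to a
    joint fit of phenotype ~ probe + covariates.
    """
    y = np.asarray(phenotype, dtype=float)
    mask = ~np.isnan(y)
    y = y[mask]
    M = np.asarray(values, dtype=float)[:, mask]
    n = y.shape[0]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)[mask]
        if C.ndim == 1:
            C = C[:, None]
        X = np.column_stack([np.ones(n), C])
    else:
        X = np.ones((n, 1))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient covariate design")
    q, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    ry = y - X @ q
    qm, _, _, _ = np.linalg.lstsq(X, M.T, rcond=None)
    RM = M - (X @ qm).T
    df = n - X.shape[1] - 1
    sxx = np.sum(RM * RM, axis=1)
    sxy = RM @ ry
    beta = sxy / np.maximum(sxx, 1e-300)
    rss = float(ry @ ry) - beta * sxy
    s2 = rss / df
    se = np.sqrt(s2 / np.maximum(sxx, 1e-300))
    t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return pd.DataFrame({"effect": beta, "se": se, "stat": t,
                         "p": np.clip(p, np.nextafter(0, 1), 1.0),
                         "df": float(df), "n": n})


def group_probes(scan: pd.DataFrame, config: MomentConfig | None = None,
                 min_size: int = 1) -> ComponentGrouping:
    """Bin probes into groups by scan P-value cut points.

    Group 0 holds the most associated probes (P below the first cut).  A
    group that is empty, or smaller than ``min_size`` (see
    ``MomentConfig.min_component_probes``), is merged into its neighbour
    with a logged warning.
    """
    config = config or MomentConfig()
    p = scan["p"].to_numpy()
    edges = (0.0,) + tuple(config.p_cuts) + (1.0001,)
    labels = np.digitize(p, edges[1:-1], right=False)
    for g in range(config.n_groups - 1, -1, -1):
        count = int(np.sum(labels == g))
        if 0 < count < min_size and labels.max() > 0:
            logger.warning("group %d has %d probes (< %d); merging with "
                           "neighbour", g, count, min_size)
            labels[labels == g] = g + 1 if g == 0 else g - 1
    # re-densify labels
    uniq = np.unique(labels)
    remap = {u: i for i, u in enumerate(uniq)}
    labels = np.array([remap[v] for v in labels])
    m = int(labels.max()) + 1
    return ComponentGrouping(labels=labels, m=m, window_bp=config.window_bp)


def _standardize_probes(values: np.ndarray) -> np.ndarray:
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (values - mu) / sd


def build_component_matrices(values: np.ndarray, grouping: ComponentGrouping,
                             target: int,
                             positions: pd.DataFrame | None = None,
                             window_bp: int | None = None,
                             ) -> list[np.ndarray | None]:
    """Per-group methylome relationship matrices excluding the target window.

    Group g's matrix is Z_g Z_g' / p_g over standardised group-g probes that
    are not the target and not within ``window_bp`` of it (same chromosome).
    A group emptied by the exclusion yields None (component dropped).
    """
    window = grouping.window_bp if window_bp is None else window_bp
    Z = _standardize_probes(np.asarray(values, dtype=float))
    p = Z.shape[0]
    excluded = np.zeros(p, dtype=bool)
    excluded[target] = True
    if positions is not None and window > 0:
        chrom = positions["chrom"].to_numpy()
        pos = positions["start"].to_numpy()
        same = chrom == chrom[target]
        excluded |= same & (np.abs(pos - pos[target]) <= window)
    out: list[np.ndarray | None] = []
    for g in range(grouping.m):
        idx = np.where((grouping.labels == g) & ~excluded)[0]
        if idx.size == 0:
            out.append(None)
            continue
        Zg = Z[idx]
        out.append((Zg.T @ Zg) / idx.size)
    return out


class _ComponentCache:
    """Full-group matrices with rank-1 downdating for per-target exclusion."""

    def __init__(self, values: np.ndarray, grouping: ComponentGrouping,
                 positions: pd.DataFrame | None):
        self.Z = _standardize_probes(np.asarray(values, dtype=float))
        self.grouping = grouping
        self.positions = positions
        self.full = []
        self.counts = []
        for g in range(grouping.m):
            idx = np.where(grouping.labels == g)[0]
            Zg = self.Z[idx]
            self.full.append(Zg.T @ Zg)
            self.counts.append(idx.size)
        if positions is not None:
            self.chrom = positions["chrom"].to_numpy()
            self.pos = positions["start"].to_numpy()
        else:
            self.chrom = None

    def excluded_for(self, target: int) -> np.ndarray:
        p = self.Z.shape[0]
        excl = np.zeros(p, dtype=bool)
        excl[target] = True
        if self.chrom is not None and self.grouping.window_bp > 0:
            same = self.chrom == self.chrom[target]
            excl |= same & (np.abs(self.pos - self.pos[target])
                            <= self.grouping.window_bp)
        return excl

    def matrices(self, target: int) -> list[np.ndarray | None]:
        excl = self.excluded_for(target)
        out = []
        for g in range(self.grouping.m):
            in_g = self.grouping.labels == g
            drop = np.where(in_g & excl)[0]
            remaining = self.counts[g] - drop.size
            if remaining == 0:
                out.append(None)
                continue
            M = self.full[g]
            if drop.size:
                Zd = self.Z[drop]
                M = M - Zd.T @ Zd
            out.append(M / remaining)
        return out


class _SingleComponentMoment:
    """Exact per-target REML for the one-component case in O(n) per step.

    With a single methylome relationship matrix, excluding the target (and
    its window) is a small-rank downdate of the full-probe matrix.  The full
    matrix is eigendecomposed once; in its eigenbasis every V-solve, trace
    and determinant needed by the AI-REML score equations reduces to
    diagonal operations plus a k x k Woodbury correction, where k is the
    number of excluded probes.  Results match the dense path to numerical
    precision.
    """

    def __init__(self, cache: _ComponentCache, X_base: np.ndarray, y: np.ndarray):
        self.cache = cache
        self.p_total = cache.Z.shape[0]
        M = cache.full[0] / cache.counts[0]
        w, Q = np.linalg.eigh(M)
        self.w = np.maximum(w, 0.0)
        self.Q = Q
        self.Xr = Q.T @ X_base                 # base design without the target
        self.yr = Q.T @ y
        self.Zr = cache.Z @ Q                  # probe loadings in eigenbasis
        self.n = y.shape[0]

    def fit(self, target: int, target_values: np.ndarray, *, init=None,
            tol=1e-6, max_iter=50) -> MomentFit:
        n = self.n
        excl = np.where(self.cache.excluded_for(target))[0]
        k = excl.size
        p_eff = self.p_total - k
        c = self.p_total / p_eff
        G = self.Zr[excl].T / np.sqrt(p_eff)   # n x k: downdate factors
        xr = np.column_stack([self.Xr, self.Q.T @ target_values])
        p = xr.shape[1]
        vary = max(float(np.var(self.yr)), 1e-12)
        floor = vary * 1e-8
        sig = (np.maximum(np.asarray(init, dtype=float), floor) if init is not None
               else np.array([0.1 * vary, 0.9 * vary]))

        from .reml import _ai_step

        def solve(d, Sk, Gd, v):
            # (D - s GG')^-1 v via Woodbury; Gd = D^-1 G, Sk = inv(I/s - G'D^-1 G)
            dv = v / d if v.ndim == 1 else v / d[:, None]
            return dv + Gd @ (Sk @ (G.T @ dv))

        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            s1, se = sig
            d = s1 * c * self.w + se
            s = s1
            Gd = G / d[:, None]
            inner = np.eye(k) / max(s, 1e-300) - G.T @ Gd
            Sk = np.linalg.inv(inner) if k else np.zeros((0, 0))
            U = solve(d, Sk, Gd, xr)
            xtvx = xr.T @ U
            B = np.linalg.inv(xtvx)
            beta = B @ (U.T @ self.yr)
            Py = solve(d, Sk, Gd, self.yr) - U @ beta
            # diag of V^-1 in the eigenbasis
            diag_vi = 1.0 / d
            if k:
                T = Gd @ Sk
                diag_vi = diag_vi + np.einsum("nk,nk->n", T, Gd)
            # component A = cW - GG'; residual A = I
            def trace_via(diag_fn_w):
                return float(np.sum(diag_vi * diag_fn_w))
            ViG = solve(d, Sk, Gd, G) if k else G
            tr_vi_A = c * trace_via(self.w) - (float(np.sum(G * ViG)) if k else 0.0)
            tr_vi_I = trace_via(np.ones(n))
            UtWU = (U * (c * self.w)[:, None]).T @ U - \
                ((U.T @ G) @ (G.T @ U) if k else 0.0)
            tr_pa_A = tr_vi_A - float(np.sum(B * UtWU))
            tr_pa_I = tr_vi_I - float(np.sum(B * (U.T @ U)))
            vA = c * self.w * Py - (G @ (G.T @ Py) if k else 0.0)
            score = np.array([
                -0.5 * (tr_pa_A - float(Py @ vA)),
                -0.5 * (tr_pa_I - float(Py @ Py)),
            ])
            vvecs = [vA, Py]
            AI = np.empty((2, 2))
            for i in range(2):
                v = vvecs[i]
                pv = solve(d, Sk, Gd, v) - U @ (B @ (U.T @ v))
                for j in range(i, 2):
                    AI[i, j] = AI[j, i] = 0.5 * float(vvecs[j] @ pv)
            new, score_ok = _ai_step(sig, score, AI, floor, vary, tol, n)
            move = np.max(np.abs(new - sig)) / vary
            sig = new
            if score_ok or move < tol:
                converged = True
                break

        s1, se = sig
        d = s1 * c * self.w + se
        Gd = G / d[:, None]
        inner = np.eye(k) / max(s1, 1e-300) - G.T @ Gd
        Sk = np.linalg.inv(inner) if k else np.zeros((0, 0))
        U = solve(d, Sk, Gd, xr)
        xtvx = xr.T @ U
        B = np.linalg.inv(xtvx)
        beta = B @ (U.T @ self.yr)
        eff, se_b = float(beta[-1]), float(np.sqrt(B[-1, -1]))
        df = n - p
        if converged:
            stat = eff / se_b
            pval = float(2.0 * stats.t.sf(abs(stat), df))
        else:
            stat, pval = np.nan, np.nan
        return MomentFit(effect=eff, se=se_b, stat=stat, p=pval, sigma2=sig,
                         converged=converged, n_components=1)


def moment_test_probe(phenotype: np.ndarray, target_mvalues: np.ndarray,
                      covariates: np.ndarray | None,
                      cell_counts: np.ndarray | None,
                      component_matrices: list[np.ndarray | None],
                      *, tol: float = 1e-6, max_iter: int = 50,
                      init: np.ndarray | None = None,
                      freeze: bool = False) -> MomentFit:
    """REML fit of the variance components and Wald test of the target probe.

    ``freeze`` skips the REML iterations and evaluates the GLS fixed-effect
    test at the supplied ``init`` variances (approximation mode).
    """
    y = np.asarray(phenotype, dtype=float)
    n = y.shape[0]
    cols = [np.ones(n)]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        cols.append(C)
    if cell_counts is not None:
        CC = np.asarray(cell_counts, dtype=float)
        if CC.ndim == 1:
            CC = CC[:, None]
        cols.append(CC)
    t = np.asarray(target_mvalues, dtype=float)
    cols.append(t[:, None])
    X = np.column_stack([c if c.ndim == 2 else c[:, None] for c in cols])
    covs = [m for m in component_matrices if m is not None]
    if init is not None and len(init) != len(covs) + 1:
        init = None
        freeze = False
    if freeze:
        if init is None:
            raise ValueError("freeze=True requires init variances")
        fit = fit_airelm(y, X, covs, tol=tol, max_iter=0, init=init)
    else:
        fit = fit_airelm(y, X, covs, tol=tol, max_iter=max_iter, init=init)
        if not fit.converged:
            fit = fit_airelm(y, X, covs, tol=tol, max_iter=max_iter)  # HE restart
    j = X.shape[1] - 1
    eff, se = float(fit.beta[j]), float(fit.beta_se[j])
    df = n - X.shape[1]
    if fit.converged:
        stat = eff / se
        p = float(2.0 * stats.t.sf(abs(stat), df))
    else:
        stat, p = np.nan, np.nan
    return MomentFit(effect=eff, se=se, stat=stat, p=p, sigma2=fit.sigma2,
                     converged=fit.converged, n_components=len(covs))


def run_mwas2(matrix: MValueMatrix, phenotype: pd.Series | np.ndarray,
              covariates: pd.DataFrame | np.ndarray | None = None,
              cell_counts: pd.DataFrame | np.ndarray | None = None,
              config: MomentConfig | None = None,
              *, n_pcs: int = 20, standardize_continuous: bool = True,
              targets: list[int] | None = None) -> pd.DataFrame:
    """Whole MWAS 2 engine: scan -> group -> per-target MOMENT test.

    ``targets`` restricts the expensive per-probe mixed-model stage to a
    subset of probe indices (the scan and grouping always use all probes).
    When ``config.exact`` is False, variance components are estimated once
    without any exclusion and frozen across targets (flagged in the output).
    """
    from .mwas1 import compute_methylome_pcs

    config = config or MomentConfig()
    y = np.asarray(phenotype, dtype=float)
    mask = ~np.isnan(y)
    y = y[mask]
    vals_all = matrix.values[:, mask]
    valsu = np.unique(y)
    is_binary = valsu.size <= 2 and set(valsu).issubset({0.0, 1.0})
    if standardize_continuous and not is_binary:
        y = (y - y.mean()) / y.std()
    cov_arr = None
    if covariates is not None:
        cov_arr = (covariates.to_numpy(dtype=float)
                   if isinstance(covariates, pd.DataFrame) else
                   np.asarray(covariates, dtype=float))
        if cov_arr.ndim == 1:
            cov_arr = cov_arr[:, None]
        cov_arr = cov_arr[mask]
    if n_pcs > 0:
        pcs = compute_methylome_pcs(vals_all, n_pcs)
        cov_arr = pcs if cov_arr is None else np.hstack([cov_arr, pcs])
    cells = None
    if cell_counts is not None:
        cells = (cell_counts.to_numpy(dtype=float)
                 if isinstance(cell_counts, pd.DataFrame) else
                 np.asarray(cell_counts, dtype=float))
        if cells.ndim == 1:
            cells = cells[:, None]
        cells = cells[mask]

    scan = initial_scan(vals_all, y, cov_arr)
    min_size = (config.min_component_probes if config.min_component_probes
                is not None else y.shape[0])
    grouping = group_probes(scan, config, min_size=min_size)
    cache = _ComponentCache(vals_all, grouping, matrix.positions)

    frozen_init = None
    if not config.exact:
        # target-free fit: components from all probes, no exclusions
        full = [cache.full[g] / cache.counts[g] for g in range(grouping.m)]
        base_cols = [np.ones(y.shape[0])]
        if cov_arr is not None:
            base_cols.append(cov_arr)
        if cells is not None:
            base_cols.append(cells)
        Xb = np.column_stack([c if np.ndim(c) == 2 else np.asarray(c)[:, None]
                              for c in base_cols])
        frozen = fit_airelm(y, Xb, full, tol=config.reml_tol,
                            max_iter=config.reml_max_iter)
        frozen_init = frozen.sigma2

    fast = None
    if config.exact and grouping.m == 1:
        base_cols = [np.ones(y.shape[0])]
        if cov_arr is not None:
            base_cols.append(cov_arr)
        if cells is not None:
            base_cols.append(cells)
        Xb = np.column_stack([c if np.ndim(c) == 2 else np.asarray(c)[:, None]
                              for c in base_cols])
        fast = _SingleComponentMoment(cache, Xb, y)

    idx_list = list(range(len(matrix.cpg_ids))) if targets is None else list(targets)
    rows = []
    warm = None
    for j in idx_list:
        if fast is not None:
            fit = fast.fit(j, vals_all[j], tol=config.reml_tol,
                           max_iter=config.reml_max_iter, init=warm)
            if fit.converged:
                warm = fit.sigma2
        elif config.exact:
            comps = cache.matrices(j)
            fit = moment_test_probe(y, vals_all[j], cov_arr, cells, comps,
                                    tol=config.reml_tol,
                                    max_iter=config.reml_max_iter, init=warm)
            if fit.converged:
                warm = fit.sigma2
        else:
            comps = cache.matrices(j)
            n_active = sum(m is not None for m in comps)
            if n_active == grouping.m:
                fit = moment_test_probe(y, vals_all[j], cov_arr, cells, comps,
                                        tol=config.reml_tol, init=frozen_init,
                                        freeze=True)
            else:   # a component was dropped: fall back to a fresh fit
                fit = moment_test_probe(y, vals_all[j], cov_arr, cells, comps,
                                        tol=config.reml_tol,
                                        max_iter=config.reml_max_iter)
        rows.append({"cpg_id": matrix.cpg_ids[j], "effect": fit.effect,
                     "se": fit.se, "stat": fit.stat, "p": fit.p,
                     "n": int(y.shape[0]), "n_components": fit.n_components,
                     "converged": fit.converged})
    table = pd.DataFrame(rows)
    pos = matrix.positions.set_index("cpg_id")
    table.insert(1, "chrom", pos.loc[table["cpg_id"], "chrom"].to_numpy())
    table.insert(2, "pos", pos.loc[table["cpg_id"], "start"].to_numpy())
    table["engine"] = "mwas2"
    table["approx"] = not config.exact
    return table
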
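"""Methylation profile scores and their evaluation.

A profile score for a target sample is the sum over discovery-selected CpGs
of discovery effect size times the sample's M-value, with CpGs selected at a
discovery P-value threshold (the seven standard thresholds run from 1e-7 to
1e-1).  Binary outcomes are evaluated by the Nagelkerke R-square increment
of the score over a covariate-only logistic model with a likelihood-ratio
P-value; continuous outcomes by the adjusted R-square increment of a linear
model with an F-test.  Significant prediction is judged against a Bonferroni
gate of alpha divided by the number of phenotypes examined (0.05/8 by
default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (1e-7, 1e-6, 1e-5, 1e-4, 1e-3, 1e-2, 1e-1)


@dataclass
class ProfileScore:
    scores: pd.Series                 # per target sample
    n_cpgs: int
    threshold: float | None
    n_missing: int = 0                # selected CpGs absent from the target matrix


@dataclass
class ScoreEvaluation:
    r2: float
    p: float
    threshold: float | None
    kind: str                         # "nagelkerke" | "adjusted"
    n: int


def select_sites(discovery_stats: pd.DataFrame, p_threshold: float) -> pd.DataFrame:
    """CpGs with discovery P strictly below the threshold, with their effects."""
    sel = discovery_stats.loc[discovery_stats["p"] < p_threshold,
                              ["cpg_id", "effect", "p"]]
    return sel.reset_index(drop=True)


def profile_score(effects: pd.Series | pd.DataFrame,
                  target_matrix: pd.DataFrame,
                  threshold: float | None = None,
                  discovery_samples=None) -> ProfileScore:
    """Weighted sum of target M-values over the selected CpGs.

    ``effects`` maps cpg_id -> discovery effect (a Series, or a frame with
    cpg_id/effect columns); ``target_matrix`` is CpG x sample.  Selected CpGs
    absent from the target matrix are skipped with a logged count; zero
    overlap is an error.  Passing ``discovery_samples`` enables the leakage
    guard: any sample id shared with the target matrix raises.
    """
    if isinstance(effects, pd.DataFrame):
        effects = effects.set_index("cpg_id")["effect"]
    if len(effects) == 0:
        raise ValueError("empty site selection: nothing to score")
    if discovery_samples is not None:
        shared = set(discovery_samples) & set(target_matrix.columns)
        if shared:
            raise ValueError(f"discovery/target sample overlap: {sorted(shared)[:5]}")
    present = effects.index.intersection(target_matrix.index)
    n_missing = len(effects) - len(present)
    if len(present) == 0:
        raise ValueError("no selected CpG is present in the target matrix")
    if n_missing:
        logger.info("profile_score: %d selected CpGs absent from target", n_missing)
    w = effects.loc[present]
    scores = target_matrix.loc[present].T @ w
    return ProfileScore(scores=scores, n_cpgs=len(present), threshold=threshold,
                        n_missing=n_missing)


def _nagelkerke_increment(outcome: np.ndarray, score: np.ndarray,
                          covariates: np.ndarray | None) -> tuple[float, float]:
    """Nagelkerke R2 of the score's increment over the covariate-only model.

    R2 = (1 - exp((2/n)(ll0 - ll1))) / (1 - exp((2/n) ll0)), with ll0 the
    covariate-only log-likelihood; P from the 1-df likelihood-ratio test.
    """
    import statsmodels.api as sm

    n = outcome.shape[0]
    X0 = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), covariates])
    X1 = np.column_stack([X0, score])
    try:
        fit0 = sm.Logit(outcome, X0).fit(disp=False, maxiter=200)
        fit1 = sm.Logit(outcome, X1).fit(disp=False, maxiter=200)
    except Exception as exc:  # pragma: no cover - statsmodels raises variously
        raise ValueError(
            "logistic fit failed (perfect separation? try fewer covariates "
            f"or a larger sample): {exc}") from exc
    ll0, ll1 = fit0.llf, fit1.llf
    denom = 1.0 - np.exp(2.0 / n * ll0)
    r2 = float((1.0 - np.exp(2.0 / n * (ll0 - ll1))) / denom) if denom != 0 else 0.0
    lr = max(2.0 * (ll1 - ll0), 0.0)
    p = float(stats.chi2.sf(lr, 1)) if lr > 0 else 1.0
    return max(r2, 0.0), p


def evaluate_binary(score: pd.Series | np.ndarray, outcome: pd.Series | np.ndarray,
                    covariates=None, threshold: float | None = None,
                    ) -> ScoreEvaluation:
    """Nagelkerke R2 increment of the score for a binary outcome."""
    s = np.asarray(score, dtype=float)
    y = np.asarray(outcome, dtype=float)
    cov = None if covariates is None else np.asarray(covariates, dtype=float)
    if cov is not None and cov.ndim == 1:
        cov = cov[:, None]
    mask = ~np.isnan(s) & ~np.isnan(y)
    if cov is not None:
        mask &= ~np.isnan(cov).any(axis=1)
        cov = cov[mask]
    s, y = s[mask], y[mask]
    if s.std() == 0:
        return ScoreEvaluation(r2=0.0, p=1.0, threshold=threshold,
                               kind="nagelkerke", n=int(s.size))
    r2, p = _nagelkerke_increment(y, s, cov)
    return ScoreEvaluation(r2=r2, p=p, threshold=threshold,
                           kind="nagelkerke", n=int(s.size))


def evaluate_continuous(score: pd.Series | np.ndarray,
                        outcome: pd.Series | np.ndarray,
                        covariates=None, threshold: float | None = None,
                        ) -> ScoreEvaluation:
    """Adjusted R2 increment of the score for a continuous outcome (F-test P)."""
    s = np.asarray(score, dtype=float)
    y = np.asarray(outcome, dtype=float)
    cov = None if covariates is None else np.asarray(covariates, dtype=float)
    if cov is not None and cov.ndim == 1:
        cov = cov[:, None]
    mask = ~np.isnan(s) & ~np.isnan(y)
    if cov is not None:
        mask &= ~np.isnan(cov).any(axis=1)
        cov = cov[mask]
    s, y = s[mask], y[mask]
    n = y.shape[0]
    if np.var(y) == 0:
        raise ValueError("outcome has zero variance")

    def _adj_r2_rss(X):
        q, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ q
        rss = float(resid @ resid)
        tss = float(((y - y.mean()) ** 2).sum())
        p_params = X.shape[1]
        r2 = 1.0 - rss / tss
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p_params)
        return adj, rss, p_params

    X0 = np.ones((n, 1)) if cov is None else np.column_stack([np.ones(n), cov])
    X1 = np.column_stack([X0, s])
    adj0, rss0, p0 = _adj_r2_rss(X0)
    adj1, rss1, p1 = _adj_r2_rss(X1)
    df2 = n - p1
    if rss1 <= 0:
        p_val = 0.0
    else:
        f = (rss0 - rss1) / 1.0 / (rss1 / df2)
        p_val = float(stats.f.sf(f, 1, df2))
    return ScoreEvaluation(r2=float(adj1 - adj0), p=p_val, threshold=threshold,
                           kind="adjusted", n=int(n))


def threshold_sweep(discovery_stats: pd.DataFrame, target_matrix: pd.DataFrame,
                    outcome: pd.Series, covariates=None,
                    thresholds=DEFAULT_THRESHOLDS, *,
                    binary: bool | None = None,
                    alpha_family: float = 0.05, n_phenotypes: int = 8,
                    discovery_samples=None) -> pd.DataFrame:
    """Evaluate the score at every threshold; flag the best-R2 threshold.

    Significance of each evaluation is judged against the family-wise gate
    alpha_family / n_phenotypes (0.05/8 = 6.25e-3 by default).  Thresholds
    with an empty selection are reported with missing R2/P.
    """
    y = outcome.loc[target_matrix.columns] if isinstance(outcome, pd.Series) else \
        pd.Series(np.asarray(outcome), index=target_matrix.columns)
    if binary is None:
        vals = set(pd.unique(y.dropna()))
        binary = vals.issubset({0, 1, 0.0, 1.0})
    gate = alpha_family / n_phenotypes
    rows = []
    for thr in thresholds:
        sel = select_sites(discovery_stats, thr)
        if sel.empty:
            rows.append({"threshold": thr, "n_cpgs": 0, "r2": np.nan,
                         "p": np.nan, "significant": False})
            continue
        ps = profile_score(sel, target_matrix, threshold=thr,
                           discovery_samples=discovery_samples)
        ev = (evaluate_binary if binary else evaluate_continuous)(
            ps.scores, y, covariates, threshold=thr)
        rows.append({"threshold": thr, "n_cpgs": ps.n_cpgs, "r2": ev.r2,
                     "p": ev.p, "significant": bool(ev.p < gate)})
    out = pd.DataFrame(rows)
    out["best"] = False
    if out["r2"].notna().any():
        out.loc[out["r2"].idxmax(), "best"] = True
    return out
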
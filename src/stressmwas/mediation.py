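"""Product-of-coefficients mediation with a percentile bootstrap.

The mediation model follows the classic decomposition: path a from the
regression of the mediator (a CpG's M-value) on the exposure (e.g. low
birth weight), paths b and c' from the outcome model (logistic for a binary
outcome such as MDD, linear otherwise) regressing the outcome on exposure
and mediator jointly.  The indirect effect is a*b on the outcome model's
linear-predictor scale; the total effect comes from the outcome model
without the mediator.  For a linear outcome, total = direct + indirect holds
exactly on the point estimates.

Confidence intervals and P-values come from a nonparametric percentile
bootstrap over individuals with a fixed seed (2000 draws by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class MediationResult:
    a: float
    b: float
    direct: float                 # c'
    indirect: float               # a * b
    total: float
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    p: dict[str, float] = field(default_factory=dict)
    n: int = 0
    n_boot: int = 0
    binary_outcome: bool = False


def _ols_coef(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    q, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    return q


def _logit_coef(X: np.ndarray, y: np.ndarray, max_iter: int = 50) -> np.ndarray:
    """Plain Newton-Raphson logistic fit (small designs, bootstrap-friendly)."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1 - mu), 1e-9, None)
        grad = X.T @ (y - mu)
        hess = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return beta


def _paths(exposure, mediator, outcome, covariates, binary):
    n = exposure.shape[0]
    base = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), covariates])
    Xa = np.column_stack([base, exposure])
    a = _ols_coef(Xa, mediator)[-1]
    Xb = np.column_stack([base, exposure, mediator])
    Xc = np.column_stack([base, exposure])
    fit_out = _logit_coef if binary else _ols_coef
    cb = fit_out(Xb, outcome)
    c_prime, b = cb[-2], cb[-1]
    total = fit_out(Xc, outcome)[-1]
    return float(a), float(b), float(c_prime), float(total)


def mediate(exposure, mediator, outcome, covariates=None, *,
            n_boot: int = 2000, seed: int = 0,
            ci_level: float = 0.95) -> MediationResult:
    """Estimate a, b, c', indirect = a*b and total, with bootstrap CIs.

    Complete cases only; ``n_boot`` must be at least 500 for stable
    percentile intervals.  Binary outcomes (coded 0/1) are detected
    automatically and use a logistic outcome model.
    """
    if n_boot < 500:
        raise ValueError("n_boot must be at least 500")
    x = np.asarray(exposure, dtype=float)
    m = np.asarray(mediator, dtype=float)
    y = np.asarray(outcome, dtype=float)
    cov = None if covariates is None else np.asarray(covariates, dtype=float)
    if cov is not None and cov.ndim == 1:
        cov = cov[:, None]
    mask = ~np.isnan(x) & ~np.isnan(m) & ~np.isnan(y)
    if cov is not None:
        mask &= ~np.isnan(cov).any(axis=1)
        cov = cov[mask]
    x, m, y = x[mask], m[mask], y[mask]
    n = x.shape[0]
    if np.std(m) == 0:
        raise ValueError("mediator is constant")
    binary = set(np.unique(y)).issubset({0.0, 1.0})

    a, b, c_prime, total = _paths(x, m, y, cov, binary)
    indirect = a * b

    rng = np.random.default_rng(seed)
    draws = {"a": [], "b": [], "direct": [], "indirect": [], "total": []}
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        cb = None if cov is None else cov[idx]
        try:
            ab, bb, cpb, totb = _paths(x[idx], m[idx], y[idx], cb, binary)
        except Exception:
            continue
        draws["a"].append(ab)
        draws["b"].append(bb)
        draws["direct"].append(cpb)
        draws["indirect"].append(ab * bb)
        draws["total"].append(totb)

    alpha = (1.0 - ci_level) / 2.0
    ci = {}
    pvals = {}
    for key, vals in draws.items():
        arr = np.asarray(vals)
        if arr.size == 0:
            ci[key] = (np.nan, np.nan)
            pvals[key] = np.nan
            continue
        ci[key] = (float(np.quantile(arr, alpha)),
                   float(np.quantile(arr, 1.0 - alpha)))
        frac = min(np.mean(arr <= 0.0), np.mean(arr >= 0.0))
        pvals[key] = float(min(1.0, 2.0 * frac))

    return MediationResult(a=a, b=b, direct=c_prime, indirect=indirect,
                           total=total, ci=ci, p=pvals, n=n,
                           n_boot=n_boot, binary_outcome=binary)
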
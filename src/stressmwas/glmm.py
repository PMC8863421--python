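"""Phenotypic regressions with kinship random effects.

Adult mental-health outcomes are regressed on each early-life environment in
turn, adjusting for sex as a fixed effect and for relatedness through a
kinship-structured random effect.  Continuous outcomes use exact REML via an
eigendecomposition of the kinship matrix; binary outcomes use a
binomial-logit model fitted by penalised quasi-likelihood (PQL), iterating a
weighted linear mixed model on the working response.  PQL variance estimates
are known to be biased towards zero at low prevalence; fixed-effect
estimates remain serviceable at the prevalences used here.

Reported significance applies a family-wise Bonferroni gate over the number
of environments examined (alpha/8 by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .reml import fit_single_component


@dataclass
class GlmmResult:
    family: str                       # "gaussian" | "binomial-logit"
    effect: float
    se: float
    stat: float
    p: float
    sex_effect: float
    kinship_variance: float
    converged: bool
    n: int
    significant: bool = False


def _prepare(outcome, exposure, sex, kinship):
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(exposure, dtype=float)
    s = np.asarray(sex)
    if s.dtype.kind in "OUS":
        s = (s == s[0]).astype(float)     # two-level factor
    else:
        s = s.astype(float)
    mask = ~np.isnan(y) & ~np.isnan(x) & ~np.isnan(s)
    K = np.asarray(kinship, dtype=float)
    if K.shape[0] != y.shape[0]:
        raise ValueError("kinship matrix not aligned with outcome")
    w = np.linalg.eigvalsh(K)
    if w.min() < -1e-6:
        raise ValueError("kinship matrix is not positive semidefinite")
    idx = np.where(mask)[0]
    return y[idx], x[idx], s[idx], K[np.ix_(idx, idx)]


def glmm_fit(outcome, exposure, sex, kinship, *, family: str = "gaussian",
             alpha_family: float = 0.05, n_environments: int = 8,
             max_pql_iter: int = 50, tol: float = 1e-6) -> GlmmResult:
    """Mixed model of outcome ~ exposure + sex with a kinship random effect."""
    y, x, s, K = _prepare(outcome, exposure, sex, kinship)
    n = y.shape[0]
    X = np.column_stack([np.ones(n), x, s])
    gate = alpha_family / n_environments

    if family == "gaussian":
        ym, ysd = y.mean(), y.std()
        ys = (y - ym) / ysd if ysd > 0 else y
        fit = fit_single_component(ys, X, K)
        eff, se = float(fit.beta[1]) * ysd, float(fit.beta_se[1]) * ysd
        stat = eff / se
        p = float(2.0 * stats.t.sf(abs(stat), n - X.shape[1]))
        return GlmmResult(family="gaussian", effect=eff, se=se, stat=stat, p=p,
                          sex_effect=float(fit.beta[2]) * ysd,
                          kinship_variance=float(fit.sigma2[0]) * ysd ** 2,
                          converged=bool(fit.converged), n=n,
                          significant=p < gate)

    if family != "binomial-logit":
        raise ValueError(f"unknown family {family!r}")

    # PQL: iterate the working LMM  z = X b + g + eps,  Var(eps) = W^-1,
    # binomial dispersion fixed at 1.  Each iteration estimates the kinship
    # variance by REML in the W^1/2-whitened space via eigendecomposition.
    import statsmodels.api as sm
    from scipy.optimize import minimize_scalar

    glm = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    beta = np.asarray(glm.params, dtype=float)
    u = np.zeros(n)
    sigma_g = 0.1
    converged = False
    se_beta = None
    for _ in range(max_pql_iter):
        eta = X @ beta + u
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-6, None)
        z = eta + (y - mu) / w
        sw = np.sqrt(w)
        Kt = (K * sw[:, None]) * sw[None, :]
        wk, Q = np.linalg.eigh(Kt)
        wk = np.maximum(wk, 0.0)
        zt = Q.T @ (sw * z)
        Xt = Q.T @ (sw[:, None] * X)

        def neg_rll(log_s):
            s = np.exp(log_s)
            d = s * wk + 1.0
            Xd = Xt / d[:, None]
            xtvx = Xt.T @ Xd
            b = np.linalg.solve(xtvx, Xd.T @ zt)
            r = zt - Xt @ b
            _, logdet_x = np.linalg.slogdet(xtvx)
            return 0.5 * (np.sum(np.log(d)) + logdet_x + float(np.sum(r * r / d)))

        res = minimize_scalar(neg_rll, bounds=(np.log(1e-6), np.log(1e3)),
                              method="bounded", options={"xatol": 1e-8})
        sigma_g = float(np.exp(res.x))
        if sigma_g <= 1e-6 * (1 + 1e-6):
            sigma_g = 0.0
        d = sigma_g * wk + 1.0
        Xd = Xt / d[:, None]
        xtvx = Xt.T @ Xd
        B = np.linalg.inv(xtvx)
        new_beta = B @ (Xd.T @ zt)
        r = zt - Xt @ new_beta
        # BLUP in original space: u = s K W^(1/2) Q (r/d)
        u_new = sigma_g * (K @ (sw * (Q @ (r / d))))
        move = max(np.max(np.abs(new_beta - beta)), np.max(np.abs(u_new - u)))
        beta, u = new_beta, u_new
        se_beta = np.sqrt(np.diag(B))
        if move < tol * 10:
            converged = True
            break
    if se_beta is None or not converged:
        return GlmmResult(family="binomial-logit", effect=np.nan, se=np.nan,
                          stat=np.nan, p=np.nan, sex_effect=np.nan,
                          kinship_variance=sigma_g, converged=False, n=n)
    eff, se = float(beta[1]), float(se_beta[1])
    stat = eff / se
    p = float(2.0 * stats.norm.sf(abs(stat)))
    return GlmmResult(family="binomial-logit", effect=eff, se=se, stat=stat,
                      p=p, sex_effect=float(beta[2]), kinship_variance=sigma_g,
                      converged=True, n=n, significant=p < gate)
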
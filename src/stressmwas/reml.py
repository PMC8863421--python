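"""Restricted-maximum-likelihood estimation of variance components.

The models fitted throughout the package have the form

    y = X b + sum_c u_c + e,   u_c ~ N(0, sigma2_c * A_c),   e ~ N(0, sigma2_e * I)

where the ``A_c`` are known sample-by-sample covariance structures: pedigree
relationship matrices (G/K/F/C/S), batch incidence products ``Z Z'`` for plate
and blood-draw date, or methylome relationship matrices built from grouped
probes.  Estimation is by average-information (AI) REML initialised from a
Haseman-Elston (method-of-moments) regression; a one-component model with iid
residuals is dispatched to an exact eigendecomposition-based profile
likelihood.

Only the inversion of V (n^3) is cubic per iteration; all traces use the
identity tr(P A) = <V^-1, A> - tr(B . (X'V^-1 A V^-1 X)) with elementwise
products, so fitting one CpG at n ~ 500 costs a few milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize


@dataclass
class VarianceComponentFit:
    """Result of a REML fit.

    ``sigma2`` holds one entry per supplied covariance structure followed by
    the residual variance.  ``beta``/``beta_se`` are GLS fixed effects under
    the estimated V.  ``converged`` is False when the AI updates did not reach
    the tolerance within ``max_iter`` (estimates from the last iteration are
    still returned).
    """

    sigma2: np.ndarray
    beta: np.ndarray
    beta_se: np.ndarray
    converged: bool
    n_iter: int
    loglik: float | None = None
    vinv: np.ndarray | None = field(default=None, repr=False)
    resid: np.ndarray | None = field(default=None, repr=False)

    @property
    def fractions(self) -> np.ndarray:
        """Variance fractions (each component / total)."""
        total = self.sigma2.sum()
        if total <= 0:
            return np.zeros_like(self.sigma2)
        return self.sigma2 / total


def haseman_elston(y: np.ndarray, X: np.ndarray, covs: list[np.ndarray]) -> np.ndarray:
    """Method-of-moments variance components via Haseman-Elston regression.

    Regresses the cross-products of OLS residuals on the corresponding
    entries of each covariance structure (plus the identity).  Fast,
    closed-form, and a good starting point for AI-REML; estimates are clipped
    at a small positive floor.
    """
    n = y.shape[0]
    q, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    e = y - X @ q
    ee = np.outer(e, e)
    mats = covs + [np.eye(n)]
    k = len(mats)
    S = np.empty((k, k))
    rhs = np.empty(k)
    for i in range(k):
        rhs[i] = float(np.sum(mats[i] * ee))
        for j in range(i, k):
            S[i, j] = S[j, i] = float(np.sum(mats[i] * mats[j]))
    try:
        est = np.linalg.solve(S, rhs)
    except np.linalg.LinAlgError:
        est = np.full(k, np.var(e) / k)
    floor = max(np.var(e), 1e-12) * 1e-4
    return np.maximum(est, floor)


def _ai_step(sig: np.ndarray, score: np.ndarray, AI: np.ndarray,
             floor: float, vary: float, tol: float, n: int,
             ) -> tuple[np.ndarray, bool]:
    """One guarded AI update: active-set pinning at the floor, pseudo-inverse
    for flat (collinear-component) directions, step-halving for positivity.

    Returns the new variances and whether the scaled score signals
    convergence.  The score scales as n/variance, so the criterion
    max|score| * vary / n < tol is scale invariant.
    """
    pinned = (sig <= floor * 1.5) & (score < 0)
    free = ~pinned
    delta = np.zeros_like(sig)
    if free.any():
        sub = AI[np.ix_(free, free)]
        delta[free] = np.linalg.pinv(sub, rcond=1e-8, hermitian=True) @ score[free]
    # clamp each component at the floor individually (a component headed
    # negative must not strangle the whole step) and cap wild overshoots
    new = np.minimum(sig + delta, 5.0 * sig + vary)
    new = np.maximum(new, floor)
    new[pinned] = floor
    scaled_score = np.max(np.abs(score[free])) * vary / n if free.any() else 0.0
    return new, scaled_score < tol


def _canonicalize(sig: np.ndarray, gram: np.ndarray, floor: float) -> np.ndarray:
    """Resolve flat directions by attributing ambiguous variance to the residual.

    When the covariance structures (including the identity) are linearly
    dependent, V — and hence the likelihood — is constant along the null
    space of their Gram matrix, and the REML split is arbitrary.  Among the
    equivalent solutions we deterministically pick the one maximising the
    residual variance (last entry), i.e. degenerate variance is left in the
    residual rather than credited to a structured component.
    """
    w, v = np.linalg.eigh(gram)
    null = v[:, w < w.max() * 1e-10]
    if null.shape[1] == 0:
        return sig
    from scipy.optimize import linprog
    k = sig.shape[0]
    c = np.zeros(null.shape[1])
    c[:] = -null[-1]                      # maximize residual component
    res = linprog(c, A_ub=-null, b_ub=sig - floor,
                  bounds=[(None, None)] * null.shape[1], method="highs")
    if not res.success:
        return sig
    return np.maximum(sig + null @ res.x, floor)


def _reml_loglik(y, X, V):
    n, p = X.shape
    cf = linalg.cho_factor(V, lower=True)
    logdet_v = 2.0 * np.sum(np.log(np.diag(cf[0])))
    viy = linalg.cho_solve(cf, y)
    vix = linalg.cho_solve(cf, X)
    xtvx = X.T @ vix
    sign, logdet_x = np.linalg.slogdet(xtvx)
    beta = np.linalg.solve(xtvx, X.T @ viy)
    r = y - X @ beta
    quad = float(r @ linalg.cho_solve(cf, r))
    return -0.5 * (logdet_v + logdet_x + quad)


def block_structure(covs: list[np.ndarray], tol: float = 1e-12) -> list[np.ndarray] | None:
    """Connected components of the union sparsity pattern of the matrices.

    When every covariance structure is block diagonal over the same sample
    partition (independent families), V inherits the structure and can be
    inverted block by block.  Returns None when the matrices are effectively
    dense (fewer than 4 blocks).
    """
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    pattern = np.zeros(covs[0].shape, dtype=bool)
    for A in covs:
        pattern |= np.abs(A) > tol
    n_comp, labels = connected_components(csr_matrix(pattern), directed=False)
    if n_comp < 4:
        return None
    return [np.where(labels == c)[0] for c in range(n_comp)]


def _blockwise_inverse(V: np.ndarray, blocks: list[np.ndarray]) -> np.ndarray:
    Vi = np.zeros_like(V)
    for idx in blocks:
        sub = V[np.ix_(idx, idx)]
        Vi[np.ix_(idx, idx)] = np.linalg.inv(sub)
    return Vi


def fit_airelm(
    y: np.ndarray,
    X: np.ndarray,
    covs: list[np.ndarray],
    *,
    include_residual: bool = True,
    init: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 50,
    compute_loglik: bool = False,
    blocks: list[np.ndarray] | None = None,
    canonicalize: bool = False,
) -> VarianceComponentFit:
    """AI-REML for an arbitrary list of covariance structures.

    Parameters
    ----------
    y, X
        Response (n,) and fixed-effect design (n, p); X must be full rank.
    covs
        List of (n, n) symmetric PSD matrices.  When ``include_residual`` an
        iid residual component (identity) is appended automatically.
    init
        Optional starting variances (length = number of components); defaults
        to Haseman-Elston.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = y.shape[0]
    mats = list(covs) + ([np.eye(n)] if include_residual else [])
    k = len(mats)
    if init is None:
        if include_residual:
            sig = haseman_elston(y, X, list(covs))
        else:
            sig = haseman_elston(y, X, list(covs[:-1]))
    else:
        sig = np.asarray(init, dtype=float).copy()
    if sig.shape[0] != k:
        raise ValueError(f"init has {sig.shape[0]} entries, expected {k}")
    vary = max(float(np.var(y)), 1e-12)
    floor = vary * 1e-8
    sig = np.maximum(sig, floor)

    converged = max_iter == 0             # max_iter=0: evaluate GLS at init
    it = 0
    V = None
    def _invert(V):
        if blocks is not None:
            return _blockwise_inverse(V, blocks)
        try:
            cf = linalg.cho_factor(V, lower=True)
            return linalg.cho_solve(cf, np.eye(n))
        except linalg.LinAlgError:
            cf = linalg.cho_factor(V + np.eye(n) * vary * 1e-6, lower=True)
            return linalg.cho_solve(cf, np.eye(n))

    for it in range(1, max_iter + 1):
        V = sum(s * A for s, A in zip(sig, mats))
        Vi = _invert(V)
        U = Vi @ X                       # n x p
        xtvx = X.T @ U
        B = np.linalg.inv(xtvx)
        beta = B @ (U.T @ y)
        Py = Vi @ y - U @ beta           # P y
        # score and AI matrix
        score = np.empty(k)
        vvecs = []
        for i, A in enumerate(mats):
            tr_pa = float(np.sum(Vi * A)) - float(np.sum(B * (U.T @ (A @ U))))
            vi = A @ Py
            vvecs.append(vi)
            score[i] = -0.5 * (tr_pa - float(Py @ vi))
        AI = np.empty((k, k))
        for i in range(k):
            pv = Vi @ vvecs[i] - U @ (B @ (U.T @ vvecs[i]))
            for j in range(i, k):
                AI[i, j] = AI[j, i] = 0.5 * float(vvecs[j] @ pv)
        new, score_ok = _ai_step(sig, score, AI, floor, vary, tol, n)
        move = np.max(np.abs(new - sig)) / vary
        sig = new
        if score_ok or move < tol:
            converged = True
            break

    if canonicalize:
        gram = np.array([[float(np.sum(Ai * Aj)) for Aj in mats] for Ai in mats])
        sig = _canonicalize(sig, gram, floor)
    V = sum(s * A for s, A in zip(sig, mats))
    Vi = _invert(V)
    U = Vi @ X
    xtvx = X.T @ U
    B = np.linalg.inv(xtvx)
    beta = B @ (U.T @ y)
    se = np.sqrt(np.diag(B))
    resid = Vi @ (y - X @ beta)
    if include_residual:
        resid = sig[-1] * resid           # sigma2_e V^-1 (y - Xb): iid residual BLUP
    ll = _reml_loglik(y, X, V) if compute_loglik else None
    return VarianceComponentFit(
        sigma2=sig, beta=beta, beta_se=se, converged=converged, n_iter=it,
        loglik=ll, vinv=Vi, resid=resid,
    )


class BlockwiseREML:
    """AI-REML specialised to block-diagonal covariance structures.

    When every covariance matrix is block diagonal over the same sample
    partition (independent families), V inherits the structure, so every
    trace, solve and quadratic form decomposes over blocks.  Blocks are
    grouped by size and processed with batched einsum/inv, which makes one
    fit O(sum b^2) instead of O(n^3) — the intended use is thousands of
    per-CpG fits sharing the same matrices and fixed design.

    Estimates are identical to :func:`fit_airelm` (same score equations and
    AI updates) up to floating-point rounding.
    """

    def __init__(self, covs: list[np.ndarray], blocks: list[np.ndarray],
                 X: np.ndarray):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        self.n, self.p = X.shape
        self.k = len(covs) + 1
        by_size: dict[int, list[np.ndarray]] = {}
        for idx in blocks:
            by_size.setdefault(len(idx), []).append(idx)
        self.groups = []
        for b, idxs in sorted(by_size.items()):
            I = np.stack(idxs)                       # (m, b)
            mats = []
            for A in covs:
                mats.append(np.stack([A[np.ix_(i, i)] for i in idxs]))
            mats.append(np.broadcast_to(np.eye(b), (len(idxs), b, b)).copy())
            self.groups.append({
                "idx": I,
                "As": np.stack(mats),                # (k, m, b, b)
                "X": X[I],                           # (m, b, p)
            })
        self.gram = sum(np.einsum("imab,jmab->ij", g["As"], g["As"])
                        for g in self.groups)

    def _gather(self, y):
        return [y[g["idx"]] for g in self.groups]

    def fit(self, y: np.ndarray, *, init: np.ndarray | None = None,
            tol: float = 1e-6, max_iter: int = 50) -> VarianceComponentFit:
        y = np.asarray(y, dtype=float)
        k = self.k
        vary = max(float(np.var(y)), 1e-12)
        floor = vary * 1e-8
        ys = self._gather(y)
        if init is None:
            # Haseman-Elston restricted to the block entries
            X_full = np.zeros((self.n, self.p))
            for g in self.groups:
                X_full[g["idx"].ravel()] = g["X"].reshape(-1, self.p)
            qb, _, _, _ = np.linalg.lstsq(X_full, y, rcond=None)
            S = np.zeros((k, k))
            rhs = np.zeros(k)
            for g, yg in zip(self.groups, ys):
                eg = yg - g["X"] @ qb
                ee = np.einsum("ma,mb->mab", eg, eg)
                rhs += np.einsum("kmab,mab->k", g["As"], ee)
                S += np.einsum("imab,jmab->ij", g["As"], g["As"])
            try:
                sig = np.linalg.solve(S, rhs)
            except np.linalg.LinAlgError:
                sig = np.full(k, vary / k)
            sig = np.maximum(sig, floor)
        else:
            sig = np.maximum(np.asarray(init, dtype=float).copy(), floor)

        converged = max_iter == 0
        it = 0
        state = None
        for it in range(1, max_iter + 1):
            state = self._decompose(sig, ys)
            score, AI = self._score_ai(state, ys)
            new, score_ok = _ai_step(sig, score, AI, floor, vary, tol, self.n)
            move = np.max(np.abs(new - sig)) / vary
            sig = new
            if score_ok or move < tol:
                converged = True
                break
        sig = _canonicalize(sig, self.gram, floor)
        state = self._decompose(sig, ys)
        beta, B, Pys = state["beta"], state["B"], state["Py"]
        resid = np.empty(self.n)
        for g, Py in zip(self.groups, Pys):
            resid[g["idx"]] = sig[-1] * Py
        return VarianceComponentFit(
            sigma2=sig, beta=beta, beta_se=np.sqrt(np.diag(B)),
            converged=converged, n_iter=it, resid=resid)

    def _decompose(self, sig, ys):
        xtvx = np.zeros((self.p, self.p))
        uty = np.zeros(self.p)
        Vis, Us = [], []
        for g, yg in zip(self.groups, ys):
            V = np.einsum("k,kmab->mab", sig, g["As"])
            Vi = np.linalg.inv(V)
            U = Vi @ g["X"]
            xtvx += np.einsum("mbp,mbq->pq", g["X"], U)
            uty += np.einsum("mbp,mb->p", U, yg)
            Vis.append(Vi)
            Us.append(U)
        B = np.linalg.inv(xtvx)
        beta = B @ uty
        Pys = []
        for g, yg, Vi, U in zip(self.groups, ys, Vis, Us):
            Viy = np.einsum("mab,mb->ma", Vi, yg)
            Pys.append(Viy - U @ beta)
        return {"Vi": Vis, "U": Us, "B": B, "beta": beta, "Py": Pys}

    def _score_ai(self, state, ys):
        k = self.k
        B = state["B"]
        score = np.zeros(k)
        vvecs = [[] for _ in range(k)]
        for g, Vi, U, Py in zip(self.groups, state["Vi"], state["U"],
                                state["Py"]):
            AU = np.einsum("kmab,mbp->kmap", g["As"], U)
            for i in range(k):
                tr_vi = np.einsum("mab,mab->", Vi, g["As"][i])
                uau = np.einsum("map,maq->pq", U, AU[i])
                tr_pa = tr_vi - float(np.sum(B * uau))
                v = np.einsum("mab,mb->ma", g["As"][i], Py)
                vvecs[i].append(v)
                score[i] += -0.5 * (tr_pa - float(np.sum(Py * v)))
        AI = np.zeros((k, k))
        for i in range(k):
            # P v_i accumulated across groups
            utv = np.zeros(self.p)
            for U, v in zip(state["U"], vvecs[i]):
                utv += np.einsum("mbp,mb->p", U, v)
            butv = B @ utv
            for gi, (Vi, U, v) in enumerate(zip(state["Vi"], state["U"],
                                                vvecs[i])):
                pv = np.einsum("mab,mb->ma", Vi, v) - U @ butv
                for j in range(i, k):
                    AI[i, j] += 0.5 * float(np.sum(vvecs[j][gi] * pv))
        AI = AI + np.triu(AI, 1).T
        return score, AI


def fit_airelm_lowrank(
    y: np.ndarray,
    X: np.ndarray,
    Zs: list[np.ndarray],
    *,
    init: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> VarianceComponentFit:
    """AI-REML for random-intercept components given as incidence factors.

    Each component's covariance is Z_i Z_i' (crossed random intercepts such
    as plate and blood-draw date); an iid residual is always included.  The
    Woodbury identity keeps every iteration O(n q + q^3) with q the total
    number of levels, so per-CpG fits are effectively free compared to the
    dense path.  Identical estimates to ``fit_airelm`` on the expanded
    matrices (same score equations, same updates).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    kq = [Z.shape[1] for Z in Zs]
    q = sum(kq)
    Z = np.hstack(Zs)
    starts = np.cumsum([0] + kq)
    blocks = [np.arange(starts[i], starts[i + 1]) for i in range(len(Zs))]
    k = len(Zs) + 1                      # + residual

    G = Z.T @ Z
    vary = max(float(np.var(y)), 1e-12)
    floor = vary * 1e-8

    if init is None:
        # Haseman-Elston on the factor representation
        qb, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        e = y - X @ qb
        S = np.empty((k, k))
        rhs = np.empty(k)
        zte = Z.T @ e
        for i in range(k - 1):
            bi = blocks[i]
            rhs[i] = float(zte[bi] @ zte[bi])
            for j in range(i, k - 1):
                bj = blocks[j]
                S[i, j] = S[j, i] = float(np.sum(G[np.ix_(bi, bj)] ** 2))
            S[i, k - 1] = S[k - 1, i] = float(np.trace(G[np.ix_(bi, bi)]))
        rhs[k - 1] = float(e @ e)
        S[k - 1, k - 1] = float(n)
        try:
            sig = np.linalg.solve(S, rhs)
        except np.linalg.LinAlgError:
            sig = np.full(k, np.var(e) / k)
        sig = np.maximum(sig, floor)
    else:
        sig = np.maximum(np.asarray(init, dtype=float).copy(), floor)

    converged = max_iter == 0
    it = 0
    for it in range(1, max_iter + 1):
        s_e = sig[-1]
        dinv = np.concatenate([np.full(kq[i], s_e / sig[i]) for i in range(len(Zs))])
        Sw = np.linalg.inv(np.diag(dinv) + G)
        ZSZt = lambda v: Z @ (Sw @ (Z.T @ v))         # noqa: E731
        Viy = (y - ZSZt(y)) / s_e
        U = (X - Z @ (Sw @ (Z.T @ X))) / s_e
        xtvx = X.T @ U
        B = np.linalg.inv(xtvx)
        beta = B @ (U.T @ y)
        Py = Viy - U @ beta
        W = Z.T @ U                                    # q x p
        zp = Z.T @ Py
        score = np.empty(k)
        vvecs = []
        for i in range(len(Zs)):
            bi = blocks[i]
            Gi = G[:, bi]
            tr_vi = (np.trace(G[np.ix_(bi, bi)]) - float(np.sum(Gi * (Sw @ Gi)))) / s_e
            Wi = W[bi]
            tr_pa = tr_vi - float(np.sum(B * (Wi.T @ Wi)))
            ti = zp[bi]
            vvecs.append(Z[:, bi] @ ti)
            score[i] = -0.5 * (tr_pa - float(ti @ ti))
        tr_vi_e = (n - float(np.sum(Sw * G))) / s_e
        tr_pa_e = tr_vi_e - float(np.sum(B * (U.T @ U)))
        vvecs.append(Py)
        score[-1] = -0.5 * (tr_pa_e - float(Py @ Py))
        AI = np.empty((k, k))
        for i in range(k):
            v = vvecs[i]
            pv = (v - ZSZt(v)) / s_e - U @ (B @ (U.T @ v))
            for j in range(i, k):
                AI[i, j] = AI[j, i] = 0.5 * float(vvecs[j] @ pv)
        new, score_ok = _ai_step(sig, score, AI, floor, vary, tol, n)
        move = np.max(np.abs(new - sig)) / vary
        sig = new
        if score_ok or move < tol:
            converged = True
            break

    s_e = sig[-1]
    dinv = np.concatenate([np.full(kq[i], s_e / sig[i]) for i in range(len(Zs))])
    Sw = np.linalg.inv(np.diag(dinv) + G)
    Viy = (y - Z @ (Sw @ (Z.T @ y))) / s_e
    U = (X - Z @ (Sw @ (Z.T @ X))) / s_e
    xtvx = X.T @ U
    B = np.linalg.inv(xtvx)
    beta = B @ (U.T @ y)
    Py = Viy - U @ beta
    return VarianceComponentFit(
        sigma2=sig, beta=beta, beta_se=np.sqrt(np.diag(B)), converged=converged,
        n_iter=it, resid=s_e * Py,
    )


def fit_single_component(
    y: np.ndarray,
    X: np.ndarray,
    K: np.ndarray | None = None,
    *,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
    bracket: tuple[float, float] = (1e-6, 1e6),
) -> VarianceComponentFit:
    """Exact REML for y = Xb + g + e with g ~ N(0, s2g K), e ~ N(0, s2e I).

    Rotates by the eigenvectors of K once (pass ``eig=(w, Q)`` to reuse a
    precomputed decomposition across many fits) and profiles the REML
    likelihood over the variance ratio with Brent search.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if eig is None:
        if K is None:
            raise ValueError("provide K or its eigendecomposition")
        w, Q = np.linalg.eigh(K)
    else:
        w, Q = eig
    w = np.maximum(w, 0.0)
    yr = Q.T @ y
    Xr = Q.T @ X

    def neg_restricted_ll(log_ratio: float) -> float:
        lam = np.exp(log_ratio)           # s2g / s2e
        d = lam * w + 1.0
        Xd = Xr / d[:, None]
        xtvx = Xr.T @ Xd
        beta = np.linalg.solve(xtvx, Xd.T @ yr)
        r = yr - Xr @ beta
        rss = float(np.sum(r * r / d))
        s2e = rss / (n - p)
        _, logdet_x = np.linalg.slogdet(xtvx)
        ll = -0.5 * (np.sum(np.log(d)) + (n - p) * np.log(s2e) + logdet_x + (n - p))
        return -ll

    lo, hi = np.log(bracket[0]), np.log(bracket[1])
    res = optimize.minimize_scalar(neg_restricted_ll, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-8})
    lam = float(np.exp(res.x))
    # boundary handling: ratio pinned at the bracket edge means ~no genetic variance
    d = lam * w + 1.0
    Xd = Xr / d[:, None]
    xtvx = Xr.T @ Xd
    B = np.linalg.inv(xtvx)
    beta = B @ (Xd.T @ yr)
    r = yr - Xr @ beta
    s2e = float(np.sum(r * r / d)) / (n - p)
    s2g = lam * s2e
    if lam <= bracket[0] * (1 + 1e-6):
        s2g = 0.0
    se = np.sqrt(np.diag(B) * s2e)
    resid = Q @ (r / d)                    # equals s2e * V^-1 (y - Xb)
    return VarianceComponentFit(
        sigma2=np.array([s2g, s2e]), beta=beta, beta_se=se, converged=res.success,
        n_iter=int(res.nfev), loglik=float(-res.fun), resid=resid,
    )
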
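"""Linear mixed models with crossed random intercepts.

The model is

    y = X beta + sum_k Z_k u_k + e,    u_k ~ N(0, sigma2_k I),
    e ~ N(0, sigma2 W^-1)

with ``W`` diagonal prior weights (identity unless PQL supplies working
weights).  Only random intercepts are supported -- exactly what herd data
need (cow, mob, sire, farm, year as grouping factors) -- which lets the
likelihood be profiled down to a q x q problem (q = total number of group
levels) via the Woodbury identity:

    V* = W^-1 + Z D Z',   D = diag(gamma_k I),  gamma_k = sigma2_k / sigma2
    V*^-1 = W - W Z D^1/2 M^-1 D^1/2 Z' W,  M = I + D^1/2 Z'WZ D^1/2

All cross-products (Z'WZ, Z'WX, ...) are computed once, so each likelihood
evaluation costs O(q^3) regardless of n.  beta and sigma2 are profiled out;
the variance ratios gamma are optimised by L-BFGS-B on their square roots
(so the boundary gamma = 0, a singular fit, is reachable).

ML is used for model comparison (LRT, AIC, BIC), REML for final estimates.
Satterthwaite degrees of freedom for a contrast c'beta follow the standard
recipe: df = 2 (c'Cc)^2 / Var(c'Cc), with the variance obtained from the
gradient of C(theta) = Var(beta_hat) in the natural variance parameters and
the inverse observed information of the (RE)ML log-likelihood, both by
central finite differences.

Logit-link models for 0-1 bounded responses are fitted by penalised
quasi-likelihood (PQL): iteratively reweighted working LMMs with unit prior
weights, the standard first-order approximation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp
from scipy import optimize, special, stats

_GAMMA_TINY = 1e-8  # below this a variance ratio is reported as boundary/singular


class ConvergenceError(RuntimeError):
    pass


def _encode_factor(codes) -> tuple[np.ndarray, int]:
    codes = np.asarray(codes)
    _, inv = np.unique(codes, return_inverse=True)
    return inv, int(inv.max()) + 1


@dataclasses.dataclass
class _Workspace:
    """Cross-products that make likelihood evaluations n-free."""

    n: int
    p: int
    K: int
    q: int
    block: list[slice]          # slice of each factor in the q dimension
    A: np.ndarray               # Z'WZ (q,q)
    B: np.ndarray               # Z'WX (q,p)
    b: np.ndarray               # Z'Wy (q,)
    XtWX: np.ndarray
    XtWy: np.ndarray
    ytWy: float
    sumlogw: float
    Z: sp.csr_matrix
    X: np.ndarray
    y: np.ndarray
    w: np.ndarray

    def d_vector(self, gamma: np.ndarray) -> np.ndarray:
        d = np.empty(self.q)
        for k, sl in enumerate(self.block):
            d[sl] = gamma[k]
        return d

    def core(self, gamma: np.ndarray):
        """Everything the profiled likelihood needs, at variance ratios gamma."""
        if self.q:
            sq = np.sqrt(self.d_vector(gamma))
            M = np.eye(self.q) + (sq[:, None] * self.A) * sq[None, :]
            L = sla.cholesky(M, lower=True)
            logdetM = 2.0 * np.log(np.diag(L)).sum()
            sB = sq[:, None] * self.B
            sb = sq * self.b
            MiB = sla.cho_solve((L, True), sB)
            Mib = sla.cho_solve((L, True), sb)
            XtVX = self.XtWX - sB.T @ MiB
            XtVy = self.XtWy - sB.T @ Mib
            yVy = self.ytWy - sb @ Mib
        else:
            logdetM = 0.0
            XtVX, XtVy, yVy = self.XtWX, self.XtWy, self.ytWy
        logdetV = logdetM - self.sumlogw
        cf = sla.cho_factor(XtVX)
        beta = sla.cho_solve(cf, XtVy)
        quad = float(yVy - beta @ XtVy)
        logdetXtVX = 2.0 * np.log(np.diag(cf[0])).sum()
        return beta, quad, logdetV, logdetXtVX, XtVX


def _profiled_loglik(ws: _Workspace, gamma: np.ndarray, reml: bool) -> float:
    _, quad, logdetV, logdetXtVX, _ = ws.core(gamma)
    quad = max(quad, 1e-300)
    if reml:
        m = ws.n - ws.p
        s2 = quad / m
        return -0.5 * (m * np.log(2 * np.pi * s2) + logdetV + logdetXtVX + m)
    s2 = quad / ws.n
    return -0.5 * (ws.n * np.log(2 * np.pi * s2) + logdetV + ws.n)


def _loglik_natural(ws: _Workspace, theta: np.ndarray, reml: bool) -> float:
    """(RE)ML log-likelihood at natural theta = (sigma2, sigma2_1..K)."""
    s2 = theta[0]
    gamma = theta[1:] / s2
    _, quad, logdetV, logdetXtVX, _ = ws.core(gamma)
    if reml:
        m = ws.n - ws.p
        return -0.5 * (m * np.log(2 * np.pi) + m * np.log(s2) + logdetV
                       + logdetXtVX + quad / s2)
    return -0.5 * (ws.n * np.log(2 * np.pi) + ws.n * np.log(s2) + logdetV
                   + quad / s2)


@dataclasses.dataclass
class LMMFit:
    """A fitted random-intercepts mixed model."""

    xnames: list
    factor_names: list
    beta: np.ndarray
    vcov_beta: np.ndarray
    sigma2: float
    vc: dict                     # named variance components sigma2_k
    gamma: np.ndarray            # variance ratios
    loglik: float
    reml: bool
    n: int
    p: int
    converged: bool
    singular: bool
    ws: _Workspace
    link: str = "identity"       # "logit" for PQL fits
    pql: bool = False

    @property
    def df_model(self) -> int:
        """Parameters counted for AIC/BIC: fixed + variance components + residual."""
        return self.p + len(self.factor_names) + 1

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.df_model

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.df_model * np.log(self.n)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov_beta))

    # -- prediction ---------------------------------------------------------

    def blups(self) -> np.ndarray:
        ws = self.ws
        r = ws.y - ws.X @ self.beta
        if not ws.q:
            return np.zeros(0)
        t = ws.Z.T @ (ws.w * r)
        d = ws.d_vector(self.gamma)
        sq = np.sqrt(d)
        M = np.eye(ws.q) + (sq[:, None] * ws.A) * sq[None, :]
        u = d * (t - ws.A @ (sq * sla.solve(M, sq * t, assume_a="pos")))
        return u

    def fitted(self) -> np.ndarray:
        eta = self.ws.X @ self.beta
        if self.ws.q:
            eta = eta + self.ws.Z @ self.blups()
        return eta

    def scaled_residuals(self) -> np.ndarray:
        """Conditional (Pearson) residuals divided by the residual SD."""
        e = self.ws.y - self.fitted()
        return e * np.sqrt(self.ws.w) / np.sqrt(self.sigma2)

    # -- inference ----------------------------------------------------------

    def contrast_variance(self, c: np.ndarray, theta: np.ndarray) -> float:
        """c' Var(beta_hat) c at natural variance parameters theta."""
        s2 = theta[0]
        gamma = np.clip(theta[1:] / s2, 0.0, None)
        *_, XtVX = self.ws.core(gamma)
        Ci = sla.solve(XtVX, c, assume_a="pos")
        return float(s2 * (c @ Ci))

    def _theta(self) -> np.ndarray:
        return np.concatenate([[self.sigma2], self.sigma2 * self.gamma])

    def vcov_theta(self) -> np.ndarray:
        """Asymptotic covariance of the natural variance parameters (cached)."""
        cached = getattr(self, "_vcov_theta", None)
        if cached is not None:
            return cached
        theta = self._theta()
        K1 = len(theta)
        h = np.maximum(1e-4 * np.abs(theta), 1e-10)
        H = np.empty((K1, K1))
        f0 = _loglik_natural(self.ws, theta, self.reml)

        def f(t):
            return _loglik_natural(self.ws, np.maximum(t, 1e-12), self.reml)

        for i in range(K1):
            for j in range(i, K1):
                if i == j:
                    tp = theta.copy(); tp[i] += h[i]
                    tm = theta.copy(); tm[i] -= h[i]
                    H[i, i] = (f(tp) - 2 * f0 + f(tm)) / h[i] ** 2
                else:
                    tpp = theta.copy(); tpp[i] += h[i]; tpp[j] += h[j]
                    tpm = theta.copy(); tpm[i] += h[i]; tpm[j] -= h[j]
                    tmp = theta.copy(); tmp[i] -= h[i]; tmp[j] += h[j]
                    tmm = theta.copy(); tmm[i] -= h[i]; tmm[j] -= h[j]
                    H[i, j] = H[j, i] = (
                        f(tpp) - f(tpm) - f(tmp) + f(tmm)
                    ) / (4 * h[i] * h[j])
        self._vcov_theta = np.linalg.pinv(-H, hermitian=True)
        return self._vcov_theta

    def satterthwaite_df(self, c: np.ndarray) -> float:
        theta = self._theta()
        K1 = len(theta)
        h = np.maximum(1e-4 * np.abs(theta), 1e-10)
        # gradient of c'C(theta)c
        g = np.empty(K1)
        for i in range(K1):
            tp = theta.copy(); tp[i] += h[i]
            tm = theta.copy(); tm[i] = max(tm[i] - h[i], 1e-12)
            g[i] = (self.contrast_variance(c, tp)
                    - self.contrast_variance(c, tm)) / (tp[i] - tm[i])
        denom = float(g @ self.vcov_theta() @ g)
        num = self.contrast_variance(c, theta)
        if denom <= 0:
            return float(self.n - self.p)
        df = 2.0 * num**2 / denom
        return float(np.clip(df, 1.0, self.n - self.p))

    def contrast(self, c: np.ndarray):
        """(estimate, se, df, t, p) for the linear combination c'beta."""
        c = np.asarray(c, float)
        est = float(c @ self.beta)
        se = float(np.sqrt(c @ self.vcov_beta @ c))
        df = self.satterthwaite_df(c)
        t = est / se if se > 0 else np.nan
        p = 2.0 * stats.t.sf(abs(t), df) if np.isfinite(t) else np.nan
        return est, se, df, t, p

    def coef_table(self):
        import pandas as pd

        rows = []
        for j, name in enumerate(self.xnames):
            c = np.zeros(self.p)
            c[j] = 1.0
            est, se, df, t, p = self.contrast(c)
            rows.append({"term": name, "estimate": est, "se": se,
                         "df": df, "t": t, "p": p})
        return pd.DataFrame(rows)


def fit_lmm(y, X, factors: dict, weights=None, reml: bool = True,
            xnames=None) -> LMMFit:
    """Fit a random-intercepts LMM.

    Parameters
    ----------
    y, X:
        Response vector and fixed-effects design matrix.
    factors:
        Mapping ``name -> group codes`` (length-n arrays); each contributes a
        random intercept per level.  Factors with fewer than 2 levels are
        rejected.
    weights:
        Optional prior precision weights (PQL working weights).
    reml:
        REML (default) or ML.
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    n, p = X.shape
    if len(y) != n:
        raise ValueError("y and X disagree on n")
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    names = list(factors)
    enc = []
    offset = 0
    block = []
    cols = []
    for name in names:
        codes, nl = _encode_factor(factors[name])
        if len(codes) != n:
            raise ValueError(f"factor {name!r} has wrong length")
        if nl < 2:
            raise ValueError(f"random factor {name!r} needs >= 2 levels")
        enc.append(codes)
        block.append(slice(offset, offset + nl))
        cols.append(codes + offset)
        offset += nl
    q = offset
    if q:
        rows = np.tile(np.arange(n), len(names))
        Z = sp.csr_matrix(
            (np.ones(n * len(names)), (rows, np.concatenate(cols))), shape=(n, q)
        )
        Wz = Z.multiply(w[:, None]).tocsr()
        A = (Z.T @ Wz).toarray()
        B = Z.T @ (w[:, None] * X)
        bvec = Z.T @ (w * y)
    else:
        Z = sp.csr_matrix((n, 0))
        A = np.zeros((0, 0))
        B = np.zeros((0, p))
        bvec = np.zeros(0)
    ws = _Workspace(
        n=n, p=p, K=len(names), q=q, block=block, A=A, B=np.asarray(B),
        b=np.asarray(bvec).ravel(), XtWX=X.T @ (w[:, None] * X),
        XtWy=X.T @ (w * y), ytWy=float(y @ (w * y)),
        sumlogw=float(np.log(w).sum()), Z=Z, X=X, y=y, w=w,
    )

    if ws.K == 0:
        beta, quad, logdetV, logdetXtVX, XtVX = ws.core(np.zeros(0))
        s2 = quad / (n - p) if reml else quad / n
        ll = _profiled_loglik(ws, np.zeros(0), reml)
        return LMMFit(
            xnames=list(xnames) if xnames is not None else [f"x{j}" for j in range(p)],
            factor_names=[], beta=beta, vcov_beta=s2 * np.linalg.inv(XtVX),
            sigma2=s2, vc={}, gamma=np.zeros(0), loglik=ll, reml=reml, n=n, p=p,
            converged=True, singular=False, ws=ws,
        )

    def neg(delta):
        return -_profiled_loglik(ws, delta**2, reml)

    best = None
    for s in (1.0, 0.3, 0.05):
        res = optimize.minimize(neg, np.full(ws.K, s), method="L-BFGS-B",
                                bounds=[(0.0, 1e3)] * ws.K,
                                options={"maxiter": 500})
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    converged = bool(best.success)
    # delta = sqrt(gamma) makes gamma = 0 an artificial stationary point, so
    # always polish derivative-free from a point nudged off the boundary
    polish = optimize.minimize(neg, np.maximum(np.abs(best.x), 0.02),
                               method="Nelder-Mead",
                               options={"xatol": 1e-8, "fatol": 1e-10,
                                        "maxiter": 2000})
    if polish.fun <= best.fun + 1e-10:
        best = polish
        converged = converged or bool(polish.success)
    gamma = np.abs(best.x) ** 2
    beta, quad, logdetV, logdetXtVX, XtVX = ws.core(gamma)
    s2 = quad / (n - p) if reml else quad / n
    ll = -best.fun
    vc = {name: float(s2 * gamma[k]) for k, name in enumerate(names)}
    return LMMFit(
        xnames=list(xnames) if xnames is not None else [f"x{j}" for j in range(p)],
        factor_names=names, beta=beta,
        vcov_beta=s2 * np.linalg.inv(XtVX), sigma2=s2, vc=vc, gamma=gamma,
        loglik=float(ll), reml=reml, n=n, p=p, converged=converged,
        singular=bool(np.any(gamma < _GAMMA_TINY)), ws=ws,
    )


def lrt(full: LMMFit, reduced: LMMFit):
    """ML likelihood-ratio test of nested models: (stat, df, p).

    Both fits must be ML.  The plain chi-square reference is used even when
    the tested parameters sit on the boundary (conservative for variance
    components).
    """
    if full.reml or reduced.reml:
        raise ValueError("LRT requires ML fits")
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    df = full.df_model - reduced.df_model
    if df <= 0:
        raise ValueError("models are not nested in the expected direction")
    return stat, df, float(stats.chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# PQL for logit-link bounded responses
# ---------------------------------------------------------------------------

def fit_pql_logit(y, X, factors: dict, reml: bool = True, xnames=None,
                  max_iter: int = 50, tol: float = 1e-6) -> LMMFit:
    """Binomial-logit mixed model on a (0,1) response by PQL.

    Iteratively fits weighted LMMs to the working response
    ``z = eta + (y - mu)/(mu(1-mu))`` with working weights ``mu(1-mu)``
    (unit prior weights).  The returned fit is the converged working model
    with ``link='logit'``; its criteria are quasi-likelihood quantities and
    are comparable only between PQL fits of the same response.
    """
    y = np.clip(np.asarray(y, float), 1e-4, 1 - 1e-4)
    eta = special.logit(y)
    fit = None
    for _ in range(max_iter):
        mu = special.expit(eta)
        wt = np.clip(mu * (1 - mu), 1e-6, None)
        z = eta + (y - mu) / wt
        fit = fit_lmm(z, X, factors, weights=wt, reml=reml, xnames=xnames)
        eta_new = fit.fitted()
        if np.max(np.abs(eta_new - eta)) < tol:
            eta = eta_new
            break
        eta = eta_new
    fit.link = "logit"
    fit.pql = True
    return fit
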
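"""Single-component GREML estimation of narrow-sense heritability.

Model: y = X b + g + e with g ~ N(0, sigma2_g K) and e ~ N(0, sigma2_e I).
The restricted likelihood is profiled down to the variance ratio
gamma = sigma2_g / sigma2_e via a single eigendecomposition of K, then
maximized over log(gamma) by a coarse grid plus Brent refinement; the
one-component restricted likelihood is unimodal in practice, so this is
robust without derivatives.  h2 = sigma2_g / (sigma2_g + sigma2_e), with a
standard error from the observed information at the optimum (delta method).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .relatedness import KinshipMatrix

__all__ = ["HeritabilityEstimate", "greml", "greml_profile"]

LOG_RATIO_BOUNDS = (np.log(1e-6), np.log(1e6))


@dataclass
class HeritabilityEstimate:
    h2: float
    se_h2: float
    sigma2_g: float
    sigma2_e: float
    loglik_reml: float
    boundary: bool = False
    n: int = 0

    def __repr__(self):
        flag = " (boundary)" if self.boundary else ""
        return (f"HeritabilityEstimate(h2={self.h2:.3f} +/- {self.se_h2:.3f}, "
                f"n={self.n}{flag})")


def _prepare(y, K, X):
    y = np.asarray(y, dtype=float).ravel()
    if isinstance(K, KinshipMatrix):
        Kv = K.values
    else:
        Kv = np.asarray(K, dtype=float)
    n = y.size
    if Kv.shape != (n, n):
        raise ValueError("kinship dimension does not match y")
    if X is None:
        X = np.ones((n, 1))
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design X is rank deficient")
    lam, U = np.linalg.eigh(Kv)
    if lam.min() < -1e-8 * max(lam.max(), 1.0):
        raise ValueError("kinship matrix is not positive semidefinite")
    lam = np.clip(lam, 0.0, None)
    if np.ptp(lam) < 1e-10 * max(lam.max(), 1.0):
        raise ValueError("kinship is proportional to the identity: genetic and "
                         "residual variance are not separable")
    # scale K to mean diagonal 1 (trace/n): sigma2_g is then the
    # per-individual genetic variance and h2 is invariant to the global
    # scale of K
    lam = lam / lam.mean()
    return y, X, lam, U


def _profile_ll(log_gamma, lam, yt, Xt):
    """Restricted log-likelihood profiled over sigma2_e, up to a constant."""
    gamma = np.exp(log_gamma)
    h = gamma * lam + 1.0
    n, p = Xt.shape
    Xw = Xt / h[:, None]
    XtHX = Xt.T @ Xw
    sign, logdet_xhx = np.linalg.slogdet(XtHX)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(XtHX, Xw.T @ yt)
    r = yt - Xt @ beta
    rss = float(r @ (r / h))
    if rss <= 0:
        return -np.inf
    df = n - p
    return -0.5 * (df * np.log(rss / df) + np.sum(np.log(h)) + logdet_xhx + df)


def _estimates_at(log_gamma, lam, yt, Xt):
    gamma = np.exp(log_gamma)
    h = gamma * lam + 1.0
    n, p = Xt.shape
    Xw = Xt / h[:, None]
    beta = np.linalg.solve(Xt.T @ Xw, Xw.T @ yt)
    r = yt - Xt @ beta
    sigma2_e = float(r @ (r / h)) / (n - p)
    return gamma * sigma2_e, sigma2_e, beta


def _reml_ll_components(sg2, se2, lam, yt, Xt):
    """Unprofiled restricted log-likelihood in (sigma2_g, sigma2_e)."""
    v = sg2 * lam + se2
    if np.any(v <= 0):
        return -np.inf
    Xw = Xt / v[:, None]
    XtVX = Xt.T @ Xw
    sign, logdet_xvx = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(XtVX, Xw.T @ yt)
    r = yt - Xt @ beta
    return -0.5 * (np.sum(np.log(v)) + logdet_xvx + float(r @ (r / v)))


def greml(y, K, X=None, compute_se: bool = True) -> HeritabilityEstimate:
    """REML estimate of h2 from a genomic relationship matrix.

    Parameters
    ----------
    y : array
        Trait values (no missing).
    K : KinshipMatrix or array
        PSD genetic relationship matrix aligned with ``y``.
    X : array, optional
        Fixed covariates (a column of ones is used when omitted).
    """
    y, X, lam, U = _prepare(y, K, X)
    scale = float(np.std(y))
    if scale <= 0:
        raise ValueError("trait has zero variance")
    ys = y / scale  # exact scale equivariance: c*y gives identical gamma
    yt = U.T @ ys
    Xt = U.T @ X
    lo, hi = LOG_RATIO_BOUNDS
    grid = np.linspace(lo, hi, 41)
    vals = np.array([_profile_ll(g, lam, yt, Xt) for g in grid])
    i = int(np.argmax(vals))
    boundary = i in (0, len(grid) - 1)
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(lambda g: -_profile_ll(g, lam, yt, Xt),
                                   bounds=(a, b), method="bounded",
                                   options={"xatol": 1e-10})
    log_gamma = float(res.x)
    if _profile_ll(grid[i], lam, yt, Xt) > -res.fun:
        log_gamma = float(grid[i])
    boundary = boundary or log_gamma <= lo + 1e-6 or log_gamma >= hi - 1e-6
    sg2, se2, _ = _estimates_at(log_gamma, lam, yt, Xt)
    sg2 *= scale ** 2
    se2 *= scale ** 2
    h2 = sg2 / (sg2 + se2)
    # on the raw-trait scale and with the same constant as greml_profile,
    # so the two are directly comparable
    yt = U.T @ y
    ll = _profile_ll(log_gamma, lam, yt, Xt)
    se_h2 = np.nan
    if compute_se:
        se_h2 = _se_h2(sg2, se2, lam, yt, Xt)
        if boundary and not np.isfinite(se_h2):
            se_h2 = np.nan
    return HeritabilityEstimate(h2=float(h2), se_h2=float(se_h2),
                                sigma2_g=float(sg2), sigma2_e=float(se2),
                                loglik_reml=float(ll), boundary=bool(boundary),
                                n=y.size)


def _se_h2(sg2, se2, lam, yt, Xt) -> float:
    """Delta-method SE of h2 from the observed information in (sg2, se2)."""
    scale = max(sg2 + se2, 1e-12)
    step = 1e-4 * scale

    def ll(p):
        return _reml_ll_components(p[0], p[1], lam, yt, Xt)

    p0 = np.array([sg2, se2])
    if np.any(p0 - step <= 0):  # boundary: observed information undefined
        return np.nan
    Hm = np.zeros((2, 2))
    for i in range(2):
        for j in range(i, 2):
            pp = p0.copy(); pp[i] += step; pp[j] += step
            pm = p0.copy(); pm[i] += step; pm[j] -= step
            mp = p0.copy(); mp[i] -= step; mp[j] += step
            mm = p0.copy(); mm[i] -= step; mm[j] -= step
            vals = [ll(pp), ll(pm), ll(mp), ll(mm)]
            if not all(np.isfinite(v) for v in vals):
                return np.nan
            Hm[i, j] = Hm[j, i] = (vals[0] - vals[1] - vals[2] + vals[3]) \
                / (4 * step ** 2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cov = np.linalg.inv(-Hm)
        except np.linalg.LinAlgError:
            return np.nan
    if not np.all(np.isfinite(cov)) or cov[0, 0] < 0 or cov[1, 1] < 0:
        return np.nan
    tot = sg2 + se2
    grad = np.array([se2 / tot ** 2, -sg2 / tot ** 2])
    var = float(grad @ cov @ grad)
    return np.sqrt(var) if var >= 0 else np.nan


def greml_profile(y, K, X=None, ratios=None):
    """Restricted log-likelihood along a grid of variance ratios.

    ``ratios`` are values of sigma2_g / sigma2_e; returns an array of the
    profiled restricted log-likelihood (same constant as the optimizer uses,
    so curves and optima are directly comparable).
    """
    if ratios is None or len(ratios) == 0:
        raise ValueError("ratio grid must be non-empty")
    y, X, lam, U = _prepare(y, K, X)
    yt = U.T @ y
    Xt = U.T @ X
    ratios = np.asarray(ratios, dtype=float)
    if np.any(ratios <= 0):
        raise ValueError("ratios must be positive")
    return np.array([_profile_ll(np.log(r), lam, yt, Xt) for r in ratios])
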
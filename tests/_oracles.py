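"""Naive, loop-based reference implementations used only as test oracles.

Everything here is written with explicit loops, dense projection matrices
and two-stage regressions -- deliberately independent of the cached
moment-matrix algebra inside the package.  Only usable at toy sizes
(n <= a few hundred).
"""

import numpy as np


def _demean(a):
    return a - a.mean(axis=0)


def proj(Z):
    """Dense projection matrix onto the column span of Z."""
    return Z @ np.linalg.pinv(Z.T @ Z) @ Z.T


def ols_loop(y, x):
    """Scalar OLS slope with intercept, accumulated elementwise."""
    n = len(y)
    xm = sum(x) / n
    ym = sum(y) / n
    sxy = sxx = 0.0
    for i in range(n):
        sxy += (x[i] - xm) * (y[i] - ym)
        sxx += (x[i] - xm) ** 2
    return sxy / sxx


def tsls_two_regressions(y, x, Z):
    """2SLS as two literal regressions: x on (1, Z), then y on (1, xhat)."""
    n = len(y)
    D = np.column_stack([np.ones(n), Z])
    first, *_ = np.linalg.lstsq(D, x, rcond=None)
    xhat = D @ first
    D2 = np.column_stack([np.ones(n), xhat])
    second, *_ = np.linalg.lstsq(D2, y, rcond=None)
    return second[1]


def gmm2_loop(y, x, Z, beta_init):
    """Two-step GMM with the weight matrix assembled element by element."""
    yc, xc, Zc = _demean(y), _demean(x), _demean(Z)
    n, J = Zc.shape
    W = np.zeros((J, J))
    for i in range(n):
        u = yc[i] - xc[i] * beta_init
        W += np.outer(Zc[i], Zc[i]) * u * u
    W /= n
    gx = Zc.T @ xc / n
    gy = Zc.T @ yc / n
    Wi = np.linalg.inv(W)
    return (gx @ Wi @ gy) / (gx @ Wi @ gx)


def cue_objective_loop(beta, y, x, Z):
    """CUE criterion assembled element by element after demeaning."""
    yc, xc, Zc = _demean(y), _demean(x), _demean(Z)
    n, J = Zc.shape
    g = np.zeros(J)
    Om = np.zeros((J, J))
    for i in range(n):
        u = yc[i] - xc[i] * beta
        g += Zc[i] * u
        Om += np.outer(Zc[i], Zc[i]) * u * u
    g /= n
    Om /= n
    return float(n * g @ np.linalg.pinv(Om, rcond=1e-10) @ g)


def ar_ratio(beta, y, x, Z):
    """Homoskedastic (Anderson-Rubin) variance-ratio objective
    n u'P u / u'u, with a dense projection matrix."""
    yc, xc, Zc = _demean(y), _demean(x), _demean(Z)
    u = yc - xc * beta
    P = proj(Zc)
    return float(len(y) * (u @ P @ u) / (u @ u))


def minimize_scalar_grid(f, lo, hi, step):
    """Coarse grid minimization followed by a parabolic refinement pass."""
    grid = np.arange(lo, hi + step, step)
    vals = np.array([f(b) for b in grid])
    return float(grid[np.argmin(vals)])


def tsls_se_homoskedastic_loop(y, x, Z):
    """Textbook homoskedastic 2SLS sandwich, computed with dense matrices."""
    yc, xc, Zc = _demean(y), _demean(x), _demean(Z)
    n = len(y)
    P = proj(Zc)
    xhat = P @ xc
    beta = (xhat @ yc) / (xhat @ xc)
    u = yc - xc * beta
    s2 = (u @ u) / n
    return beta, float(np.sqrt(s2 / (xc @ P @ xc)))


def tsls_se_robust_loop(y, x, Z):
    """Heteroskedasticity-robust 2SLS sandwich via dense matrices."""
    yc, xc, Zc = _demean(y), _demean(x), _demean(Z)
    P = proj(Zc)
    xhat = P @ xc
    beta = (xhat @ yc) / (xhat @ xc)
    u = yc - xc * beta
    meat = sum((xhat[i] * u[i]) ** 2 for i in range(len(y)))
    return beta, float(np.sqrt(meat) / (xhat @ xc))


def ols_se_loop(y, x, robust=False):
    yc, xc = _demean(y), _demean(x)
    n = len(y)
    beta = (xc @ yc) / (xc @ xc)
    u = yc - xc * beta
    if robust:
        meat = sum((xc[i] * u[i]) ** 2 for i in range(n))
        return beta, float(np.sqrt(meat) / (xc @ xc))
    s2 = (u @ u) / n
    return beta, float(np.sqrt(s2 / (xc @ xc)))


def liml_loop(y, x, Z):
    """LIML by direct scalar minimization of the variance ratio, plus the
    implied k-class estimate computed with dense matrices."""
    from scipy.optimize import minimize_scalar

    yc, xc, Zc = _demean(y), _demean(x), _demean(Z)
    b0 = tsls_two_regressions(y, x, Z)
    r = minimize_scalar(lambda b: ar_ratio(b, y, x, Z),
                        bounds=(b0 - 20, b0 + 20), method="bounded",
                        options={"xatol": 1e-12})
    return float(r.x)


def liml_se_loop(y, x, Z):
    """k-class conventional LIML standard error with dense matrices."""
    yc, xc, Zc = _demean(y), _demean(x), _demean(Z)
    n = len(y)
    P = proj(Zc)
    M = np.eye(n) - P
    W = np.column_stack([yc, xc])
    lam = np.linalg.eigvals(np.linalg.inv(W.T @ M @ W) @ (W.T @ P @ W))
    lam = np.min(np.real(lam))
    kap = 1.0 + lam
    A = xc @ xc - kap * (xc @ M @ xc)
    b = (xc @ yc - kap * (xc @ M @ yc)) / A
    u = yc - b * xc
    s2 = (u @ u) / n
    return b, float(np.sqrt(s2 / A)), kap


def bekker_se_loop(y, x, Z):
    """Bekker many-instrument variance for LIML with dense matrices."""
    yc, xc, Zc = _demean(y), _demean(x), _demean(Z)
    n = len(y)
    P = proj(Zc)
    b, _, kap = liml_se_loop(y, x, Z)
    u = yc - b * xc
    alpha = (u @ P @ u) / (u @ u)
    H = xc @ P @ xc - alpha * (xc @ xc)
    xbar = xc - u * ((u @ xc) / (u @ u))
    s2 = (u @ u) / n
    Sig = s2 * ((1 - alpha) ** 2 * (xbar @ P @ xbar)
                + alpha ** 2 * (xbar @ (np.eye(n) - P) @ xbar))
    return b, float(np.sqrt(Sig) / abs(H))


def gmm_se_loop(y, x, Z, beta):
    """Efficient-GMM asymptotic SE at ``beta`` with elementwise assembly."""
    yc, xc, Zc = _demean(y), _demean(x), _demean(Z)
    n, J = Zc.shape
    Om = np.zeros((J, J))
    for i in range(n):
        u = yc[i] - xc[i] * beta
        Om += np.outer(Zc[i], Zc[i]) * u * u
    Om /= n
    G = Zc.T @ xc / n
    return float(np.sqrt(1.0 / (n * G @ np.linalg.inv(Om) @ G)))


def nw_se_loop(y, x, Z, beta):
    """Newey-Windmeijer corrected CUE variance with dense matrices and a
    finite-difference Hessian of the loop-based objective."""
    yc, xc, Zc = _demean(y), _demean(x), _demean(Z)
    n, J = Zc.shape
    u = yc - xc * beta
    Om = np.zeros((J, J))
    C = np.zeros((J, J))
    for i in range(n):
        Om += np.outer(Zc[i], Zc[i]) * u[i] * u[i]
        C -= np.outer(Zc[i], Zc[i]) * xc[i] * u[i]
    Om /= n
    C /= n
    g = Zc.T @ u / n
    Oi = np.linalg.inv(Om)
    D = -Zc.T @ xc / n - C @ Oi @ g
    mid = n * D @ Oi @ D
    h = 1e-4 * max(1.0, abs(beta))
    f = lambda b: cue_objective_loop(b, y, x, Z)
    Hh = (f(beta + h) - 2 * f(beta) + f(beta - h)) / (h * h) / 2.0
    return float(np.sqrt(mid) / Hh)


def sargan_loop(y, x, Z, beta):
    """n R^2 of residuals regressed on (1, Z)."""
    u = y - x * beta
    n = len(y)
    D = np.column_stack([np.ones(n), Z])
    coef, *_ = np.linalg.lstsq(D, u, rcond=None)
    uhat = D @ coef
    uc = u - u.mean()
    return float(n * ((uhat - uhat.mean()) @ (uhat - uhat.mean())) / (uc @ uc))
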
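"""Standard errors, weak-instrument diagnostics and specification tests.

Conventional (fixed-``J``) asymptotic standard errors understate the
sampling variability of LIML and the CUE when many weak instruments are
used.  This module therefore provides, next to the conventional and
heteroskedasticity-robust sandwiches, the two many-instrument corrections
the estimators need for reliable Wald inference:

* ``bekker_se`` -- Bekker's (1994) many-instrument asymptotic variance for
  LIML, in the sandwich form of Hansen, Hausman and Newey (2008):
  ``V = H^{-1} Sigma H^{-1}`` with ``H = X'PX - alpha X'X``,
  ``alpha = u'Pu/u'u``, ``Sigma = s2 [(1-alpha)^2 Xb'P Xb + alpha^2 Xb'M Xb]``
  and ``Xb = X - u (u'X)/(u'u)`` the exposure purged of its component
  correlated with the structural error.  As ``J/n -> 0`` this collapses to
  the conventional variance.

* ``nw_se`` -- the Newey-Windmeijer (2009) many-weak-moment variance for the
  CUE: ``V = H^{-1} (n D'Omega^{-1} D) H^{-1}`` where ``H`` is half the
  Hessian of the CUE objective at the optimum and ``D`` is the moment
  derivative recentred by its correlation with the moments,
  ``D = G - [C_k Omega^{-1} g]_k``.  With strong instruments it reduces to
  the usual efficient-GMM variance.

The theoretical weak-instrument bias approximations are also here: for
``J > 3`` instruments the 2SLS bias is approximately
``(sigma_uv/sigma_v^2) (J-2) E[1/chi2_J(mu^2)]`` (exact inverse moment of a
noncentral chi-square with the concentration parameter ``mu^2`` as
noncentrality), increasing in ``J``; the LIML analogue
``-(sigma_uv/sigma_v^2)/mu^2`` is ``J``-free and of opposite sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, special, stats

from .data import IVData
from .estimators import EstimateResult, PINV_RCOND, cue_objective
from .exceptions import (
    DataValidationError,
    NotOveridentifiedError,
    NumericalDegeneracyError,
    UndefinedBiasError,
)

__all__ = [
    "InferenceResult", "DiagnosticsReport",
    "conventional_se", "bekker_se", "nw_se", "wald_test",
    "first_stage_diagnostics", "concentration_parameter", "expected_f",
    "bias_2sls_approx", "bias_liml_approx",
    "sargan_test", "hansen_j_test", "hausman_test",
]

#: CI critical value (normal 95%), applied at presentation level
CI_CRIT = 1.96


@dataclass
class InferenceResult:
    """Standard errors and the Wald test of ``beta = 0`` for one fit."""

    se: np.ndarray
    se_kind: str
    cov: np.ndarray
    wald_stat: float
    p_value: float
    ci_low: np.ndarray
    ci_high: np.ndarray
    fallback: bool = False


@dataclass
class DiagnosticsReport:
    """First-stage strength diagnostics for a single-exposure model."""

    f_statistic: float
    partial_r2: float
    concentration: float
    expected_f: float
    bias_2sls: float
    bias_liml: float
    n: int
    J: int


def _finish(cov: np.ndarray, beta: np.ndarray, kind: str,
            fallback: bool = False) -> InferenceResult:
    cov = np.atleast_2d(cov)
    var = np.diag(cov)
    if np.any(var <= 0) or not np.all(np.isfinite(var)):
        raise NumericalDegeneracyError(
            f"non-positive variance estimate in {kind} standard errors")
    se = np.sqrt(var)
    l = beta.shape[0]
    if l == 1:
        wald = float((beta[0] / se[0]) ** 2)
    else:
        wald = float(beta @ np.linalg.solve(cov, beta))
    p = float(stats.chi2.sf(wald, l))
    return InferenceResult(se=se, se_kind=kind, cov=cov, wald_stat=wald,
                           p_value=p, ci_low=beta - CI_CRIT * se,
                           ci_high=beta + CI_CRIT * se, fallback=fallback)


def _sigma2(result: EstimateResult, data: IVData) -> float:
    b = result.beta_hat
    return float(data.Syy - 2.0 * b @ data.Sxy + b @ data.Sxx @ b) / data.n


def conventional_se(result: EstimateResult, data: IVData,
                    robust: bool = False) -> InferenceResult:
    """Fixed-``J`` asymptotic standard errors for any family estimator.

    Homoskedastic sandwiches for OLS/2SLS, the k-class form for LIML, and
    the efficient-GMM asymptotic variance for two-step GMM and CUE (which is
    heteroskedasticity-robust by construction).  ``robust=True`` switches
    OLS/2SLS/LIML to the heteroskedasticity-robust sandwich.
    """
    if result.n != data.n or result.l != data.l or result.J != data.J:
        raise DataValidationError("result does not match the supplied data")
    b = result.beta_hat
    s2 = _sigma2(result, data)
    est = result.estimator
    if est in ("gmm2", "cue"):
        Om = data.omega(b)
        G = data.Szx / data.n
        try:
            GWG = G.T @ linalg.cho_solve(
                linalg.cho_factor(Om, check_finite=False), G, check_finite=False)
        except linalg.LinAlgError:
            GWG = G.T @ (np.linalg.pinv(Om, rcond=PINV_RCOND) @ G)
        cov = np.linalg.inv(np.atleast_2d(GWG)) / data.n
        return _finish(cov, b, "robust" if robust else "conventional")
    if est == "ols":
        H = data.Sxx
        meat = _meat(data.X, data.residuals(b)) if robust else None
    elif est == "tsls":
        H = data.XPX
        if robust:
            Xhat = data.Z @ data._zz_inv_zx
            meat = _meat(Xhat, data.residuals(b))
    elif est == "liml":
        kap = result.liml_kappa if result.liml_kappa is not None else 1.0
        H = data.Sxx - kap * (data.Sxx - data.XPX)
        if robust:
            Xhat = data.Z @ data._zz_inv_zx
            Xtil = Xhat + (1.0 - kap) * (data.X - Xhat)   # (I - kappa M) X
            meat = _meat(Xtil, data.residuals(b))
    else:
        raise ValueError(f"unknown estimator {est!r}")
    Hi = np.linalg.inv(np.atleast_2d(H))
    cov = Hi @ meat @ Hi if robust else s2 * Hi
    return _finish(cov, b, "robust" if robust else "conventional")


def _meat(A: np.ndarray, u: np.ndarray) -> np.ndarray:
    Au = A * (u * u)[:, None]
    return np.atleast_2d(Au.T @ A)


def bekker_se(result: EstimateResult, data: IVData) -> InferenceResult:
    """Bekker many-instrument corrected standard errors for LIML."""
    if result.estimator != "liml":
        raise ValueError("bekker_se applies to LIML results only")
    if data.J >= data.n:
        raise DataValidationError("many-instrument correction needs J < n")
    b = result.beta_hat
    uu = _sigma2(result, data) * data.n
    uPu = float(data.yPy - 2.0 * b @ data.XPy + b @ data.XPX @ b)
    uPu = max(uPu, 0.0)
    alpha = uPu / uu
    H = np.atleast_2d(data.XPX - alpha * data.Sxx)
    Xu = data.Sxy - data.Sxx @ b                       # X'u
    XPu = data.XPy - data.XPX @ b                      # X'Pu
    c = Xu / uu
    XbPXb = data.XPX - np.outer(XPu, c) - np.outer(c, XPu) + np.outer(c, c) * uPu
    XbXb = data.Sxx - np.outer(Xu, c) - np.outer(c, Xu) + np.outer(c, c) * uu
    XbMXb = XbXb - XbPXb
    s2 = uu / data.n
    Sig = s2 * ((1.0 - alpha) ** 2 * np.atleast_2d(XbPXb)
                + alpha ** 2 * np.atleast_2d(XbMXb))
    Hi = np.linalg.inv(H)
    return _finish(Hi @ Sig @ Hi, b, "bekker")


def nw_se(result: EstimateResult, data: IVData,
          step: float = 1e-4) -> InferenceResult:
    """Newey-Windmeijer many-weak-moment corrected standard errors for the CUE.

    Falls back to the efficient-GMM (robust) variance with a warning when the
    Hessian of the CUE objective is not positive definite at the optimum.
    """
    if result.estimator != "cue":
        raise ValueError("nw_se applies to CUE results only")
    b = result.beta_hat
    l = data.l
    Om = data.omega(b)
    g = data.moments(b)
    G = -data.Szx / data.n                              # (J, l)
    try:
        cho = linalg.cho_factor(Om, check_finite=False)
        solve = lambda v: linalg.cho_solve(cho, v, check_finite=False)
    except linalg.LinAlgError:
        Oi = np.linalg.pinv(Om, rcond=PINV_RCOND)
        solve = lambda v: Oi @ v
    # recentre the moment derivative: D_k = G_k - C_k Omega^{-1} g,
    # C_k = -(1/n) sum_i x_ik u_i z_i z_i'
    u = data.residuals(b)
    Og = solve(g)
    D = np.empty((data.J, l))
    for k in range(l):
        Zxu = data.Z * (data.X[:, k] * u)[:, None]
        Ck = -(Zxu.T @ data.Z) / data.n
        D[:, k] = G[:, k] - Ck @ Og
    mid = data.n * (D.T @ solve(D))
    H = _half_hessian(b, data, step)
    try:
        ev = np.linalg.eigvalsh(H)
        if np.any(ev <= 0):
            raise np.linalg.LinAlgError
        Hi = np.linalg.inv(H)
        cov = Hi @ np.atleast_2d(mid) @ Hi
        if np.any(np.diag(cov) <= 0):
            raise np.linalg.LinAlgError
        return _finish(cov, b, "newey_windmeijer")
    except np.linalg.LinAlgError:
        warnings.warn("CUE objective Hessian not positive definite; "
                      "falling back to the efficient-GMM variance",
                      RuntimeWarning)
        fb = conventional_se(result, data, robust=True)
        return InferenceResult(se=fb.se, se_kind="newey_windmeijer",
                               cov=fb.cov, wald_stat=fb.wald_stat,
                               p_value=fb.p_value, ci_low=fb.ci_low,
                               ci_high=fb.ci_high, fallback=True)


def _half_hessian(beta: np.ndarray, data: IVData, step: float) -> np.ndarray:
    """Central finite-difference Hessian of ``Q_CUE/2`` at ``beta``."""
    l = beta.shape[0]
    q0 = cue_objective(beta, data)
    h = step * np.maximum(1.0, np.abs(beta))
    H = np.empty((l, l))
    for i in range(l):
        ei = np.zeros(l); ei[i] = h[i]
        H[i, i] = (cue_objective(beta + ei, data) - 2.0 * q0
                   + cue_objective(beta - ei, data)) / (h[i] * h[i])
    for i in range(l):
        for j in range(i + 1, l):
            ei = np.zeros(l); ei[i] = h[i]
            ej = np.zeros(l); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                cue_objective(beta + ei + ej, data)
                - cue_objective(beta + ei - ej, data)
                - cue_objective(beta - ei + ej, data)
                + cue_objective(beta - ei - ej, data)) / (4.0 * h[i] * h[j])
    return H / 2.0


def wald_test(result: EstimateResult, inference: InferenceResult, beta0=0.0):
    """Wald test of ``beta = beta0``; chi-square with ``l`` degrees of freedom."""
    beta0 = np.broadcast_to(np.atleast_1d(np.asarray(beta0, float)),
                            result.beta_hat.shape)
    d = result.beta_hat - beta0
    if d.shape[0] == 1:
        stat = float((d[0] / inference.se[0]) ** 2)
    else:
        stat = float(d @ np.linalg.solve(inference.cov, d))
    return stat, float(stats.chi2.sf(stat, d.shape[0]))


# ---------------------------------------------------------------------------
# weak-instrument diagnostics and theoretical bias approximations
# ---------------------------------------------------------------------------

def first_stage_diagnostics(data: IVData, sigma_uv: float | None = None,
                            sigma_v2: float | None = None) -> DiagnosticsReport:
    """First-stage F, partial R-squared and implied bias approximations.

    Requires a single exposure.  The joint F statistic tests that all
    first-stage coefficients are zero; the sample concentration parameter is
    recovered as ``J (F - 1)``.  Unless ``sigma_uv``/``sigma_v2`` are given
    (e.g. known design values in a simulation), they are plugged in from the
    first-stage residual variance and its covariance with the OLS residual --
    a rough diagnostic, since the structural error is not observed.
    """
    if data.l != 1:
        raise DataValidationError("first-stage diagnostics need a single exposure")
    n, J = data.n, data.J
    ess = float(data.XPX[0, 0])
    sxx = float(data.Sxx[0, 0])
    rss = max(sxx - ess, 0.0)
    dof = n - J - (1 if data.include_intercept else 0)
    f = (ess / J) / (rss / dof)
    partial_r2 = ess / sxx
    conc = J * (f - 1.0)
    if sigma_v2 is None:
        sigma_v2 = rss / dof
    if sigma_uv is None:
        b_ols = float(data.Sxy[0] / sxx)
        v = data.X[:, 0] - data.Z @ data._zz_inv_zx[:, 0]
        u_ols = data.y - b_ols * data.X[:, 0]
        sigma_uv = float(v @ u_ols) / n
    try:
        b2 = bias_2sls_approx(J, conc, sigma_uv, sigma_v2)
    except (UndefinedBiasError, ValueError):
        b2 = np.nan
    try:
        bl = bias_liml_approx(conc, sigma_uv, sigma_v2)
    except UndefinedBiasError:
        bl = np.nan
    return DiagnosticsReport(f_statistic=f, partial_r2=partial_r2,
                             concentration=conc,
                             expected_f=conc / J + 1.0,
                             bias_2sls=b2, bias_liml=bl, n=n, J=J)


def concentration_parameter(n: int, J: int, pi: float, maf: float,
                            sigma_v2: float) -> float:
    """Concentration parameter ``mu^2 = n J pi^2 sigma_z^2 / sigma_v^2``
    for ``J`` i.i.d. biallelic variants with allele frequency ``maf``
    (genotype variance ``sigma_z^2 = 2 maf (1 - maf)``) and common
    first-stage coefficient ``pi``."""
    if not 0.0 < maf < 1.0:
        raise ValueError("maf must lie in (0, 1)")
    if sigma_v2 <= 0:
        raise ValueError("sigma_v2 must be positive")
    sigma_z2 = 2.0 * maf * (1.0 - maf)
    return n * J * pi * pi * sigma_z2 / sigma_v2


def expected_f(mu2: float, J: int) -> float:
    """Stock's approximation ``E[F] ~= mu^2/J + 1`` to the mean first-stage F."""
    if J < 1:
        raise ValueError("J must be >= 1")
    return mu2 / J + 1.0


def _inv_moment_ncchi2(df: int, nc: float) -> float:
    """Exact ``E[1/X]`` for ``X ~ chi2_df(nc)`` via the Poisson mixture series."""
    half = nc / 2.0
    K = int(half + 12.0 * np.sqrt(half + 1.0) + 50.0)
    k = np.arange(K)
    logw = -half + k * np.log(half) - special.gammaln(k + 1) if half > 0 else None
    if half == 0:
        return 1.0 / (df - 2.0)
    return float(np.sum(np.exp(logw) / (df + 2.0 * k - 2.0)))


def bias_2sls_approx(J: int, mu2: float, sigma_uv: float,
                     sigma_v2: float) -> float:
    """Approximate many-weak-instrument bias of 2SLS.

    ``(sigma_uv / sigma_v^2) * (J - 2) * E[1/chi2_J(mu^2)]`` -- proportional
    to the number of instruments and the error covariance, and inversely
    related to the concentration parameter.  The approximation is derived for
    more than three instruments; a warning is issued for ``J <= 3``.
    """
    if mu2 <= 0:
        raise UndefinedBiasError("bias approximation undefined for mu^2 <= 0")
    if J < 3:
        raise ValueError("the 2SLS bias approximation needs J >= 3")
    if J == 3:
        warnings.warn("2SLS bias approximation is derived for J > 3",
                      RuntimeWarning)
    return (sigma_uv / sigma_v2) * (J - 2.0) * _inv_moment_ncchi2(J, mu2)


def bias_liml_approx(mu2: float, sigma_uv: float, sigma_v2: float) -> float:
    """Approximate many-weak-instrument bias of LIML,
    ``-(sigma_uv/sigma_v^2) / mu^2`` -- independent of ``J`` and of opposite
    sign to the 2SLS bias."""
    if mu2 <= 0:
        raise UndefinedBiasError("bias approximation undefined for mu^2 <= 0")
    return -(sigma_uv / sigma_v2) / mu2


# ---------------------------------------------------------------------------
# specification tests
# ---------------------------------------------------------------------------

def sargan_test(result: EstimateResult, data: IVData):
    """Sargan overidentification test, ``n R^2`` of the residuals on Z.

    Assumes conditional homoskedasticity.  Returns (statistic, df, p).
    """
    if data.J <= data.l:
        raise NotOveridentifiedError("Sargan test needs J > l")
    b = result.beta_hat
    uPu = float(data.yPy - 2.0 * b @ data.XPy + b @ data.XPX @ b)
    uu = _sigma2(result, data) * data.n
    stat = data.n * max(uPu, 0.0) / uu
    df = data.J - data.l
    return stat, df, float(stats.chi2.sf(stat, df))


def hansen_j_test(result: EstimateResult, data: IVData):
    """Hansen J overidentification test (heteroskedasticity-robust):
    the continuously-updated GMM objective at the estimate.  Returns
    (statistic, df, p)."""
    if data.J <= data.l:
        raise NotOveridentifiedError("Hansen J test needs J > l")
    stat = cue_objective(result.beta_hat, data)
    df = data.J - data.l
    return stat, df, float(stats.chi2.sf(stat, df))


def hausman_test(iv_result: EstimateResult, ols_result: EstimateResult,
                 data: IVData):
    """Hausman test of exogeneity: does the IV estimate differ from OLS?

    Uses conventional homoskedastic variances; a negative variance difference
    is clamped to zero with a warning (statistic reported as 0).  Returns
    (statistic, p).
    """
    if ols_result.estimator != "ols":
        raise ValueError("second argument must be an OLS result")
    if iv_result.n != ols_result.n or iv_result.l != ols_result.l \
            or iv_result.n != data.n:
        raise DataValidationError("results were not fitted on the same data")
    d = iv_result.beta_hat - ols_result.beta_hat
    V_iv = conventional_se(iv_result, data).cov
    V_ols = conventional_se(ols_result, data).cov
    dV = V_iv - V_ols
    l = d.shape[0]
    if l == 1:
        if dV[0, 0] <= 0:
            if abs(d[0]) > 0:
                warnings.warn("negative Hausman variance difference; "
                              "statistic clamped to 0", RuntimeWarning)
            return 0.0, 1.0
        stat = float(d[0] * d[0] / dV[0, 0])
    else:
        try:
            ev = np.linalg.eigvalsh(dV)
            if np.any(ev <= 0):
                raise np.linalg.LinAlgError
            stat = float(d @ np.linalg.solve(dV, d))
        except np.linalg.LinAlgError:
            warnings.warn("Hausman variance difference not positive definite; "
                          "statistic clamped to 0", RuntimeWarning)
            return 0.0, 1.0
    return stat, float(stats.chi2.sf(stat, l))
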
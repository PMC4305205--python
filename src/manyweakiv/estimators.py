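"""The GMM family of instrumental-variable point estimators.

All estimators solve the moment conditions ``E[z_i (y_i - x_i' beta)] = 0``
by minimising a quadratic form ``Q(beta) = n g(beta)' W^{-1} g(beta)`` in the
sample moments ``g(beta) = (1/n) sum_i z_i (y_i - x_i' beta)``; they differ
only in the weight ``W``:

============  ==========================================================
OLS           instruments set equal to the exposures (z_i = x_i)
2SLS          fixed weight ``Z'Z/n``
two-step GMM  efficient weight ``Omega(beta~)`` at a preliminary estimate
CUE           ``Omega(beta)`` continuously updated inside the objective
LIML          CUE with homoskedasticity imposed, ``W = sigma^2(beta) Z'Z/n``
============  ==========================================================

LIML is computed exactly through the minimum eigenvalue of the generalized
eigenproblem on the ``[y X]`` moment matrices rather than by numerical
search; the CUE, whose objective can be multimodal with weak instruments, is
minimised from several starting values and the best local optimum is kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.optimize import minimize, minimize_scalar

from .data import IVData
from .exceptions import DegenerateDesignError, NumericalDegeneracyError

__all__ = [
    "EstimateResult",
    "fit_ols",
    "fit_2sls",
    "fit_gmm2",
    "fit_liml",
    "fit_cue",
    "cue_objective",
    "sequential_fit",
]

#: relative eigenvalue cutoff for the pseudo-inverse fallback on a singular
#: moment covariance (degenerate weight policy)
PINV_RCOND = 1e-10

#: default multiplicative grid of CUE starting values (times the two-step
#: GMM estimate), chosen to straddle local optima
CUE_START_MULTIPLIERS = (-2.0, -1.0, 0.0, 1.0, 2.0)


@dataclass
class EstimateResult:
    """Point estimate from one member of the GMM estimator family.

    Attributes
    ----------
    beta_hat : ndarray, shape (l,)
        Estimated exposure effect(s).
    estimator : str
        One of ``{"ols", "tsls", "gmm2", "liml", "cue"}``.
    objective_value : float or None
        Minimised GMM criterion ``Q(beta_hat)`` where defined (None for OLS).
        For LIML this is the homoskedastic criterion, for two-step GMM the
        criterion under its efficient weight (the Hansen J statistic).
    liml_kappa : float or None
        k-class eigenvalue ratio (LIML only); 1 for just-identified models.
    converged : bool
        False only if every CUE start failed to converge.
    intercept : float
        Implied intercept ``mean(y) - mean(x)'beta`` (0 without intercept).
    degenerate_weight : bool
        True when a singular weight matrix forced the pseudo-inverse policy.
    """

    beta_hat: np.ndarray
    estimator: str
    n: int
    J: int
    l: int
    objective_value: float | None = None
    liml_kappa: float | None = None
    converged: bool = True
    intercept: float = 0.0
    degenerate_weight: bool = False
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        self.beta_hat = np.atleast_1d(np.asarray(self.beta_hat, dtype=np.float64))


def _intercept(data: IVData, beta: np.ndarray) -> float:
    if not data.include_intercept:
        return 0.0
    return float(data.y_mean - data.X_mean @ beta)


def fit_ols(data: IVData) -> EstimateResult:
    """Least squares of the outcome on the exposures.

    Within the GMM family this is the estimator whose instruments are the
    exposures themselves; under confounding it is inconsistent for the causal
    effect and serves as the benchmark the weak-instrument bias pulls toward.
    """
    try:
        cho = linalg.cho_factor(data.Sxx, check_finite=False)
    except linalg.LinAlgError as exc:
        raise DegenerateDesignError("X'X is singular") from exc
    beta = np.atleast_1d(linalg.cho_solve(cho, data.Sxy, check_finite=False))
    return EstimateResult(beta, "ols", data.n, data.J, data.l,
                          intercept=_intercept(data, beta))


def fit_2sls(data: IVData) -> EstimateResult:
    """Two-stage least squares: ``beta = (X'P_Z X)^{-1} X'P_Z y``.

    Equivalent to GMM with weight ``Z'Z/n``; exactly reproduced by regressing
    the exposure on the instruments and the outcome on the fitted values.
    """
    XPX = data.XPX
    try:
        cho = linalg.cho_factor(XPX, check_finite=False)
    except linalg.LinAlgError as exc:
        raise DegenerateDesignError(
            "rank-deficient first stage: X'P_Z X singular") from exc
    beta = np.atleast_1d(linalg.cho_solve(cho, data.XPy, check_finite=False))
    # objective under the homoskedastic weight sigma^2 Z'Z/n: n u'P_Z u / u'u
    # (zero when just identified; this is also the Sargan statistic)
    uPu = float(data.yPy - 2.0 * beta @ data.XPy + beta @ data.XPX @ beta)
    uu = float(data.Syy - 2.0 * beta @ data.Sxy + beta @ data.Sxx @ beta)
    q = data.n * uPu / uu if uu > 0 else 0.0
    return EstimateResult(beta, "tsls", data.n, data.J, data.l,
                          objective_value=max(q, 0.0),
                          intercept=_intercept(data, beta))


def fit_gmm2(data: IVData, initial: EstimateResult | None = None) -> EstimateResult:
    """Two-step efficient GMM.

    Builds the efficient weight ``Omega(beta~) = (1/n) sum z_i z_i' u_i^2``
    from the residuals of a preliminary consistent estimate (2SLS by default)
    and solves the resulting weighted moment equations in one step.
    """
    if initial is None:
        initial = fit_2sls(data)
    if not np.all(np.isfinite(initial.beta_hat)):
        raise NumericalDegeneracyError("initial estimate is not finite")
    Om = data.omega(initial.beta_hat)
    G = data.Szx / data.n                       # (J, l), derivative sign dropped
    gy = data.Szy / data.n
    degenerate = False
    try:
        cho = linalg.cho_factor(Om, check_finite=False)
        WG = linalg.cho_solve(cho, G, check_finite=False)
        Wg = linalg.cho_solve(cho, gy, check_finite=False)
    except linalg.LinAlgError:
        cond = np.linalg.cond(Om)
        warnings.warn(
            f"singular efficient weight matrix (cond={cond:.3e}); "
            "using pseudo-inverse", RuntimeWarning)
        Oi = np.linalg.pinv(Om, rcond=PINV_RCOND)
        WG, Wg = Oi @ G, Oi @ gy
        degenerate = True
    A = G.T @ WG
    try:
        beta = np.atleast_1d(np.linalg.solve(A, G.T @ Wg))
    except np.linalg.LinAlgError as exc:
        raise DegenerateDesignError("G'W^{-1}G singular in two-step GMM") from exc
    g = data.moments(beta)
    Om_hat = data.omega(beta)
    try:
        j = float(data.n * g @ linalg.cho_solve(
            linalg.cho_factor(Om_hat, check_finite=False), g, check_finite=False))
    except linalg.LinAlgError:
        j = float(data.n * g @ (np.linalg.pinv(Om_hat, rcond=PINV_RCOND) @ g))
        degenerate = True
    return EstimateResult(beta, "gmm2", data.n, data.J, data.l,
                          objective_value=j, intercept=_intercept(data, beta),
                          degenerate_weight=degenerate,
                          extra={"weight_at": np.array(initial.beta_hat)})


def cue_objective(beta, data: IVData, centered: bool = False) -> float:
    """Continuously updated GMM criterion ``n g(beta)' Omega(beta)^{-1} g(beta)``.

    ``Omega(beta)`` is the uncentered residual-weighted instrument outer
    product ``(1/n) sum z_i z_i' u_i(beta)^2`` (set ``centered=True`` to
    subtract ``g g'``, the alternative convention).  A singular ``Omega`` --
    e.g. with identically-zero residuals -- falls back to the declared
    pseudo-inverse policy.
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=np.float64))
    if not np.all(np.isfinite(beta)):
        raise NumericalDegeneracyError("beta must be finite")
    g = data.moments(beta)
    Om = data.omega(beta)
    if centered:
        Om = Om - np.outer(g, g)
    try:
        cho = linalg.cho_factor(Om, check_finite=False)
        return float(data.n * g @ linalg.cho_solve(cho, g, check_finite=False))
    except linalg.LinAlgError:
        return float(data.n * g @ (np.linalg.pinv(Om, rcond=PINV_RCOND) @ g))


def _cue_weight_is_degenerate(beta, data: IVData) -> bool:
    try:
        linalg.cho_factor(data.omega(beta), check_finite=False)
        return False
    except linalg.LinAlgError:
        return True


def fit_cue(data: IVData, starts=None, centered: bool = False,
            xatol: float = 1e-9, bracket: float = 10.0) -> EstimateResult:
    """Continuously updating estimator (CUE).

    Minimises :func:`cue_objective` from several starting values and keeps
    the argmin with the smallest objective; ties within numerical tolerance
    are broken toward the smallest ``|beta|``.  The default starts are
    ``{-2,-1,0,1,2}`` times the two-step GMM estimate, which guards against
    the local optima the objective develops with many weak instruments.

    For one exposure a bounded derivative-free scalar search (bracket
    ``+- bracket`` around each start) is used; for several exposures each
    start is refined with a quasi-Newton minimiser.
    """
    if starts is None:
        anchor = fit_gmm2(data).beta_hat
        starts = [m * anchor for m in CUE_START_MULTIPLIERS]
    starts = [np.atleast_1d(np.asarray(s, dtype=np.float64)) for s in starts]
    obj = lambda b: cue_objective(b, data, centered=centered)

    best_beta, best_val, any_ok = None, np.inf, False
    for s in starts:
        if data.l == 1:
            r = minimize_scalar(lambda b: obj([b]),
                                bounds=(s[0] - bracket, s[0] + bracket),
                                method="bounded", options={"xatol": xatol})
            cand, val, ok = np.array([r.x]), float(r.fun), bool(r.success)
        else:
            r = minimize(obj, s, method="BFGS",
                         options={"gtol": 1e-8, "maxiter": 500})
            cand, val = np.atleast_1d(r.x), float(r.fun)
            # 'precision loss' at a flat optimum still counts as converged
            ok = bool(r.success) or (
                r.jac is not None
                and np.linalg.norm(r.jac) < 1e-4 * (1.0 + abs(val)))
        any_ok = any_ok or ok
        better = val < best_val - 1e-12
        tie = abs(val - best_val) <= 1e-12 and (
            best_beta is None or np.linalg.norm(cand) < np.linalg.norm(best_beta))
        if best_beta is None or better or tie:
            best_beta, best_val = cand, val
    if not any_ok:
        warnings.warn("no CUE start converged; returning best value found",
                      RuntimeWarning)
    return EstimateResult(best_beta, "cue", data.n, data.J, data.l,
                          objective_value=best_val, converged=any_ok,
                          intercept=_intercept(data, best_beta),
                          degenerate_weight=_cue_weight_is_degenerate(best_beta, data))


def fit_liml(data: IVData, eig_tol: float = 1e-8) -> EstimateResult:
    """Limited information maximum likelihood via the minimum-eigenvalue ratio.

    With homoskedastic weight ``sigma^2(beta) Z'Z/n`` the CUE objective
    reduces to the variance ratio ``n u(beta)'P_Z u(beta) / u(beta)'u(beta)``,
    whose minimiser is the smallest eigenvalue ``lambda`` of the pencil
    ``(W'P_Z W, W'M_Z W)`` with ``W = [y X]``.  LIML is then the k-class
    estimator at ``kappa = 1 + lambda``, stored as ``liml_kappa``.
    """
    W_PW = np.empty((data.l + 1, data.l + 1))
    W_PW[0, 0] = data.yPy
    W_PW[0, 1:] = W_PW[1:, 0] = data.XPy
    W_PW[1:, 1:] = data.XPX
    WW = np.empty_like(W_PW)
    WW[0, 0] = data.Syy
    WW[0, 1:] = WW[1:, 0] = data.Sxy
    WW[1:, 1:] = data.Sxx
    W_MW = WW - W_PW
    try:
        lam = linalg.eigh(W_PW, W_MW, eigvals_only=True,
                          subset_by_index=(0, 0), check_finite=False)[0]
    except linalg.LinAlgError as exc:
        raise NumericalDegeneracyError(
            "generalized eigenproblem for LIML failed") from exc
    if not np.isfinite(lam) or lam < -eig_tol:
        raise NumericalDegeneracyError(
            f"invalid LIML eigenvalue {lam!r} (expected >= 0)")
    lam = max(float(lam), 0.0)
    kappa = 1.0 + lam
    XMX = data.Sxx - data.XPX
    XMy = data.Sxy - data.XPy
    A = data.Sxx - kappa * XMX
    b = data.Sxy - kappa * XMy
    try:
        beta = np.atleast_1d(np.linalg.solve(A, b))
    except np.linalg.LinAlgError as exc:
        raise DegenerateDesignError("singular k-class system in LIML") from exc
    # homoskedastic CUE criterion at the optimum: n * lambda / (1 + lambda)
    q = data.n * lam / (1.0 + lam)
    return EstimateResult(beta, "liml", data.n, data.J, data.l,
                          objective_value=q, liml_kappa=kappa,
                          intercept=_intercept(data, beta))


_FITTERS = {"ols": fit_ols, "tsls": fit_2sls, "2sls": fit_2sls,
            "gmm2": fit_gmm2, "liml": fit_liml, "cue": fit_cue}


def fit(data: IVData, method: str, **kwargs) -> EstimateResult:
    """Dispatch to one of the family estimators by name."""
    try:
        f = _FITTERS[method.lower()]
    except KeyError:
        raise ValueError(f"unknown estimator {method!r}; "
                         f"choose from {sorted(set(_FITTERS))}") from None
    return f(data, **kwargs)


def sequential_fit(data: IVData, order=None, estimators=("tsls", "cue")):
    """Refit with a growing instrument set, one variant at a time.

    Mirrors the add-one-variant-at-a-time diagnostic for many-weak-instrument
    bias: for ``j = 1..J`` the model is refitted using the first ``j``
    instruments in ``order`` (default: decreasing first-stage coefficient
    magnitude, i.e. strongest variant first).  Per step the estimate,
    conventional standard error and first-stage F statistic are recorded; a
    failed fit is logged in the record rather than aborting the sweep.

    Returns a list of dicts with keys
    ``j, instrument, estimator, beta, se, f_statistic, error``.
    """
    from .inference import conventional_se, first_stage_diagnostics

    if order is None:
        pi_hat = data.solve_zz(data.Szx)[:, 0] if data.l == 1 else \
            np.linalg.norm(data.solve_zz(data.Szx), axis=1)
        order = list(np.argsort(-np.abs(pi_hat)))
    order = list(order)
    if sorted(order) != list(range(data.J)):
        raise ValueError("order must be a permutation of 0..J-1")
    bad = set(estimators) - {"tsls", "cue"}
    if bad:
        raise ValueError(f"sequential_fit supports tsls/cue, got {sorted(bad)}")

    records = []
    for j in range(1, data.J + 1):
        sub = data.subset_instruments(order[:j])
        diag = first_stage_diagnostics(sub)
        for est in estimators:
            rec = {"j": j, "instrument": order[j - 1], "estimator": est,
                   "beta": np.nan, "se": np.nan,
                   "f_statistic": diag.f_statistic, "error": None}
            try:
                res = fit(sub, est)
                inf = conventional_se(res, sub)
                rec["beta"] = float(res.beta_hat[0])
                rec["se"] = float(inf.se[0])
            except Exception as exc:  # record, keep sweeping
                rec["error"] = repr(exc)
            records.append(rec)
    return records
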
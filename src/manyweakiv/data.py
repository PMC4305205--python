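"""Core data container for instrumental-variable analyses.

``IVData`` holds one continuous outcome, ``l`` continuous exposures and ``J``
instruments (genotype dosages or allele scores) for ``n`` individuals.  All
estimators in :mod:`manyweakiv.estimators` and all inference routines in
:mod:`manyweakiv.inference` consume this container.

The intercept is handled by centering: when ``include_intercept=True`` (the
default) the outcome, exposures and instruments are demeaned once on
construction, which is algebraically identical to carrying an explicit
constant in both stages of every estimator.  Cross-moment matrices that are
reused by several estimators (``Z'Z`` and its Cholesky factor, ``Z'X``,
projections onto the instrument span, and the residual-weighted instrument
outer products needed by GMM weight matrices) are computed lazily and cached,
so that fitting the whole estimator family to one dataset touches the
``n``-length arrays only a handful of times.  This is what keeps the Monte
Carlo engine in :mod:`manyweakiv.simulate` affordable at thousands of
replications.
"""

from __future__ import annotations

from functools import cached_property

import numpy as np
from scipy import linalg

from .exceptions import DataValidationError, DegenerateDesignError

__all__ = ["IVData"]


class IVData:
    """Outcome, exposures and instruments for one IV analysis.

    Parameters
    ----------
    y : array-like, shape (n,)
        Continuous outcome.
    X : array-like, shape (n, l) or (n,)
        Continuous exposure(s).
    Z : array-like, shape (n, J) or (n,)
        Instruments (e.g. genotype counts coded 0/1/2, or allele scores).
    include_intercept : bool, default True
        Include an intercept in every first and second stage (implemented by
        demeaning all variables).

    Raises
    ------
    DataValidationError
        On missing values, shape mismatches or ``n <= J`` / ``J < l``.
    DegenerateDesignError
        If the instruments are collinear (``Z'Z`` singular after centering)
        or a column of ``Z`` is constant.
    """

    def __init__(self, y, X, Z, include_intercept: bool = True):
        y = np.asarray(y, dtype=np.float64)
        X = np.asarray(X, dtype=np.float64)
        Z = np.asarray(Z, dtype=np.float64)
        if X.ndim == 1:
            X = X[:, None]
        if Z.ndim == 1:
            Z = Z[:, None]
        if y.ndim != 1:
            raise DataValidationError("y must be one-dimensional")
        n = y.shape[0]
        if X.shape[0] != n or Z.shape[0] != n:
            raise DataValidationError(
                f"row mismatch: y has {n}, X has {X.shape[0]}, Z has {Z.shape[0]}"
            )
        for name, a in (("y", y), ("X", X), ("Z", Z)):
            if not np.all(np.isfinite(a)):
                raise DataValidationError(f"{name} contains missing or non-finite values")
        l = X.shape[1]
        J = Z.shape[1]
        if not (n > J >= l >= 1):
            raise DataValidationError(
                f"need n > J >= l >= 1, got n={n}, J={J}, l={l}"
            )
        if include_intercept:
            ptp = Z.max(axis=0) - Z.min(axis=0)
            if np.any(ptp == 0):
                j = int(np.argmin(ptp))
                raise DegenerateDesignError(
                    f"instrument column {j} is constant and collinear with the intercept"
                )
        self.include_intercept = bool(include_intercept)
        self.n, self.l, self.J = n, l, J
        self.y_raw, self.X_raw, self.Z_raw = y, X, Z
        if include_intercept:
            self.y_mean = y.mean()
            self.X_mean = X.mean(axis=0)
            self.Z_mean = Z.mean(axis=0)
            self.y = y - self.y_mean
            self.X = X - self.X_mean
            self.Z = Z - self.Z_mean
        else:
            self.y_mean = 0.0
            self.X_mean = np.zeros(l)
            self.Z_mean = np.zeros(J)
            self.y, self.X, self.Z = y, X, Z

    # ---- second-moment cache -------------------------------------------------

    @cached_property
    def Szz(self) -> np.ndarray:
        return self.Z.T @ self.Z

    @cached_property
    def _cho_zz(self):
        try:
            return linalg.cho_factor(self.Szz, check_finite=False)
        except linalg.LinAlgError as exc:
            raise DegenerateDesignError("Z'Z is singular: collinear instruments") from exc

    def solve_zz(self, B: np.ndarray) -> np.ndarray:
        """Return ``(Z'Z)^{-1} B``."""
        return linalg.cho_solve(self._cho_zz, B, check_finite=False)

    @cached_property
    def Szx(self) -> np.ndarray:
        return self.Z.T @ self.X                      # (J, l)

    @cached_property
    def Szy(self) -> np.ndarray:
        return self.Z.T @ self.y                      # (J,)

    @cached_property
    def Sxx(self) -> np.ndarray:
        return self.X.T @ self.X                      # (l, l)

    @cached_property
    def Sxy(self) -> np.ndarray:
        return self.X.T @ self.y                      # (l,)

    @cached_property
    def Syy(self) -> float:
        return float(self.y @ self.y)

    # projections onto the instrument span -------------------------------------

    @cached_property
    def _zz_inv_zx(self) -> np.ndarray:
        return self.solve_zz(self.Szx)                # (Z'Z)^{-1} Z'X

    @cached_property
    def XPX(self) -> np.ndarray:
        """``X' P_Z X`` with ``P_Z`` the projection onto the instrument span."""
        return self.Szx.T @ self._zz_inv_zx

    @cached_property
    def XPy(self) -> np.ndarray:
        return self._zz_inv_zx.T @ self.Szy

    @cached_property
    def yPy(self) -> float:
        return float(self.Szy @ self.solve_zz(self.Szy))

    # residual-weighted outer products for GMM weights -------------------------
    #
    # For a scalar exposure the GMM weight matrix at any beta is a quadratic
    # matrix polynomial: with u = y - beta*x,
    #   Omega(beta) = Z'diag(u^2)Z/n = A0 - 2*beta*A1 + beta^2*A2,
    # so the three coefficient matrices are precomputed once and every CUE
    # objective evaluation costs O(J^3) instead of O(n J^2).

    @cached_property
    def _A_mats(self):
        if self.l != 1:
            raise RuntimeError("quadratic weight cache only applies when l == 1")
        x = self.X[:, 0]
        y = self.y
        Zy = self.Z * (y * y)[:, None]
        Zxy = self.Z * (x * y)[:, None]
        Zxx = self.Z * (x * x)[:, None]
        n = self.n
        return (Zy.T @ self.Z / n, Zxy.T @ self.Z / n, Zxx.T @ self.Z / n)

    def omega(self, beta) -> np.ndarray:
        """Uncentered moment-covariance ``(1/n) sum_i z_i z_i' u_i(beta)^2``."""
        beta = np.atleast_1d(np.asarray(beta, dtype=np.float64))
        if self.l == 1:
            A0, A1, A2 = self._A_mats
            b = beta[0]
            return A0 - 2.0 * b * A1 + b * b * A2
        u = self.y - self.X @ beta
        Zu = self.Z * u[:, None]
        return Zu.T @ Zu / self.n

    def moments(self, beta) -> np.ndarray:
        """Sample moment vector ``g(beta) = (1/n) Z'(y - X beta)``."""
        beta = np.atleast_1d(np.asarray(beta, dtype=np.float64))
        return (self.Szy - self.Szx @ beta) / self.n

    def residuals(self, beta) -> np.ndarray:
        beta = np.atleast_1d(np.asarray(beta, dtype=np.float64))
        return self.y - self.X @ beta

    # ---- convenience ---------------------------------------------------------

    def with_instruments(self, Z_new) -> "IVData":
        """New ``IVData`` with the same outcome/exposures and different instruments."""
        return IVData(self.y_raw, self.X_raw, Z_new,
                      include_intercept=self.include_intercept)

    def subset_instruments(self, cols) -> "IVData":
        """Restrict to the instrument columns ``cols`` (order preserved)."""
        return self.with_instruments(self.Z_raw[:, list(cols)])

    def __repr__(self) -> str:  # pragma: no cover
        return (f"IVData(n={self.n}, l={self.l}, J={self.J}, "
                f"intercept={self.include_intercept})")
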
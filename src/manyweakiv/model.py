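"""High-level Model/Results interface.

``IVModel`` wraps an :class:`~manyweakiv.data.IVData` the way statsmodels
wraps a design matrix: build it from arrays or a DataFrame, call ``fit`` with
the estimator of choice, and receive an ``IVResults`` object carrying the
point estimate, every applicable flavour of standard error, diagnostics and
a ``summary()`` table.

Example
-------
>>> model = IVModel.from_dataframe(df, outcome="fvc", exposures="height",
...                                instruments=[c for c in df if c.startswith("rs")])
>>> res = model.fit("liml")
>>> res.params, res.std_errors("bekker")
>>> print(res.summary())
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import estimators as est
from . import inference as inf
from .data import IVData

__all__ = ["IVModel", "IVResults"]


class IVModel:
    """Linear IV model: one outcome, ``l`` exposures, ``J`` instruments."""

    def __init__(self, y, X, Z, include_intercept: bool = True,
                 exposure_names=None, instrument_names=None):
        self.data = IVData(y, X, Z, include_intercept=include_intercept)
        self.exposure_names = list(exposure_names) if exposure_names is not None \
            else [f"x{i+1}" for i in range(self.data.l)]
        self.instrument_names = list(instrument_names) if instrument_names is not None \
            else [f"z{j+1}" for j in range(self.data.J)]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, outcome: str, exposures,
                       instruments, include_intercept: bool = True) -> "IVModel":
        """Build a model from named columns of a DataFrame."""
        if isinstance(exposures, str):
            exposures = [exposures]
        instruments = list(instruments)
        missing = [c for c in [outcome, *exposures, *instruments]
                   if c not in df.columns]
        if missing:
            raise KeyError(f"columns not in DataFrame: {missing}")
        return cls(df[outcome].to_numpy(), df[list(exposures)].to_numpy(),
                   df[instruments].to_numpy(),
                   include_intercept=include_intercept,
                   exposure_names=list(exposures),
                   instrument_names=instruments)

    @classmethod
    def from_ivdata(cls, data: IVData, **names) -> "IVModel":
        m = cls.__new__(cls)
        m.data = data
        m.exposure_names = names.get(
            "exposure_names", [f"x{i+1}" for i in range(data.l)])
        m.instrument_names = names.get(
            "instrument_names", [f"z{j+1}" for j in range(data.J)])
        return m

    def fit(self, method: str = "tsls", **kwargs) -> "IVResults":
        """Fit one family estimator ('ols'|'tsls'|'gmm2'|'liml'|'cue')."""
        return IVResults(self, est.fit(self.data, method, **kwargs))

    def fit_all(self, methods=("ols", "tsls", "liml", "cue")) -> dict:
        return {m: self.fit(m) for m in methods}

    def first_stage(self, **kwargs) -> inf.DiagnosticsReport:
        """First-stage strength diagnostics (single exposure)."""
        return inf.first_stage_diagnostics(self.data, **kwargs)

    def sequential(self, order=None, estimators=("tsls", "cue")) -> pd.DataFrame:
        """Add-one-instrument-at-a-time sweep; see
        :func:`manyweakiv.estimators.sequential_fit`."""
        recs = est.sequential_fit(self.data, order=order, estimators=estimators)
        df = pd.DataFrame(recs)
        df["instrument"] = [self.instrument_names[i] for i in df["instrument"]]
        return df


class IVResults:
    """Estimation results with lazily computed standard-error flavours."""

    def __init__(self, model: IVModel, estimate: est.EstimateResult):
        self.model = model
        self.estimate = estimate
        self._inference_cache: dict[str, inf.InferenceResult] = {}

    # -- basic accessors ------------------------------------------------------

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.estimate.beta_hat, index=self.model.exposure_names)

    @property
    def estimator(self) -> str:
        return self.estimate.estimator

    @property
    def default_se_kind(self) -> str:
        """Corrected SEs where they exist (bekker for LIML, Newey-Windmeijer
        for CUE), conventional otherwise."""
        return {"liml": "bekker", "cue": "newey_windmeijer"}.get(
            self.estimator, "conventional")

    def std_errors(self, kind: str | None = None) -> pd.Series:
        return pd.Series(self._infer(kind).se, index=self.model.exposure_names)

    @property
    def bse(self) -> pd.Series:
        return self.std_errors("conventional")

    def conf_int(self, kind: str | None = None) -> pd.DataFrame:
        r = self._infer(kind)
        return pd.DataFrame({"lower": r.ci_low, "upper": r.ci_high},
                            index=self.model.exposure_names)

    def wald_test(self, beta0=0.0, kind: str | None = None):
        return inf.wald_test(self.estimate, self._infer(kind), beta0)

    @property
    def pvalues(self) -> pd.Series:
        r = self._infer("conventional")
        from scipy import stats
        z = self.estimate.beta_hat / r.se
        return pd.Series(stats.chi2.sf(z * z, 1), index=self.model.exposure_names)

    def _infer(self, kind: str | None) -> inf.InferenceResult:
        kind = kind or self.default_se_kind
        if kind not in self._inference_cache:
            data = self.model.data
            if kind == "conventional":
                r = inf.conventional_se(self.estimate, data)
            elif kind == "robust":
                r = inf.conventional_se(self.estimate, data, robust=True)
            elif kind == "bekker":
                r = inf.bekker_se(self.estimate, data)
            elif kind in ("newey_windmeijer", "nw"):
                kind = "newey_windmeijer"
                r = inf.nw_se(self.estimate, data)
            else:
                raise ValueError(f"unknown SE kind {kind!r}")
            self._inference_cache[kind] = r
        return self._inference_cache[kind]

    def available_se_kinds(self):
        kinds = ["conventional", "robust"]
        if self.estimator == "liml":
            kinds.append("bekker")
        elif self.estimator == "cue":
            kinds.append("newey_windmeijer")
        return kinds

    # -- specification tests --------------------------------------------------

    def sargan(self):
        return inf.sargan_test(self.estimate, self.model.data)

    def hansen_j(self):
        return inf.hansen_j_test(self.estimate, self.model.data)

    def hausman(self):
        ols = est.fit_ols(self.model.data)
        return inf.hausman_test(self.estimate, ols, self.model.data)

    def first_stage(self, **kwargs) -> inf.DiagnosticsReport:
        return self.model.first_stage(**kwargs)

    # -- presentation ---------------------------------------------------------

    def summary(self) -> str:
        e = self.estimate
        lines = []
        title = {"ols": "Ordinary least squares", "tsls": "Two-stage least squares",
                 "gmm2": "Two-step GMM", "liml": "LIML",
                 "cue": "Continuously updating estimator (CUE)"}[self.estimator]
        lines.append(title)
        lines.append("=" * 72)
        lines.append(f"n = {e.n}    instruments J = {e.J}    exposures l = {e.l}")
        if e.liml_kappa is not None:
            lines.append(f"k-class eigenvalue kappa = {e.liml_kappa:.6f}")
        if e.objective_value is not None:
            lines.append(f"objective Q(beta_hat) = {e.objective_value:.6g}")
        lines.append("-" * 72)
        lines.append(f"{'exposure':<14}{'estimate':>10}" +
                     "".join(f"{('se ('+k+')'):>18}" for k in self.available_se_kinds()))
        for i, name in enumerate(self.model.exposure_names):
            row = f"{name:<14}{e.beta_hat[i]:>10.4f}"
            for k in self.available_se_kinds():
                row += f"{self._infer(k).se[i]:>18.4f}"
            lines.append(row)
        r = self._infer(self.default_se_kind)
        ci = self.conf_int()
        lines.append("-" * 72)
        lines.append(f"95% CI [{self.default_se_kind}]: " + ", ".join(
            f"{name} ({lo:.4f}, {hi:.4f})"
            for name, lo, hi in zip(self.model.exposure_names,
                                    ci["lower"], ci["upper"])))
        lines.append(f"Wald (beta=0) [{r.se_kind}]: stat = {r.wald_stat:.4f}, "
                     f"p = {r.p_value:.4g}")
        if self.model.data.l == 1:
            d = self.first_stage()
            lines.append(f"first-stage F = {d.f_statistic:.2f}, "
                         f"partial R^2 = {d.partial_r2:.4f}")
        if self.model.data.J > self.model.data.l and self.estimator != "ols":
            s, df, p = self.sargan()
            j, _, pj = self.hansen_j()
            lines.append(f"Sargan = {s:.2f} (df={df}, p={p:.3g}); "
                         f"Hansen J = {j:.2f} (p={pj:.3g})")
        if self.estimator in ("tsls", "liml") :
            hs, hp = self.hausman()
            lines.append(f"Hausman vs OLS: stat = {hs:.3f}, p = {hp:.3g}")
        lines.append("=" * 72)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        b = ", ".join(f"{n}={v:.4f}" for n, v in self.params.items())
        return f"<IVResults {self.estimator}: {b}>"
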
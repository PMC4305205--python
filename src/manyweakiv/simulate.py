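"""Data-generating process and Monte Carlo engine for the many-weak-instrument
study designs.

The DGP draws, for each of ``n`` individuals, ``J`` independent genotypes
``z_ij ~ Binomial(2, maf)`` and sets

.. code-block:: text

    x_i = pi_z * sum_j z_ij + w_i + eps_xi      (first stage)
    y_i = beta * x_i + w_i + eps_yi             (outcome)

with the unobserved confounder ``w_i`` and the idiosyncratic errors all
i.i.d. standard normal.  The composite errors ``v_i = w_i + eps_xi`` and
``u_i = w_i + eps_yi`` therefore have ``sigma_v^2 = sigma_u^2 = 2`` and
``sigma_uv = 1``: the confounder induces the positive error correlation that
biases OLS (and, with many weak instruments, 2SLS) upward when ``beta = 0``.

The three standard designs hold the concentration parameter fixed at
``mu^2 = n J pi_z^2 sigma_z^2 / sigma_v^2 = 56.70`` while spreading it over
more, individually weaker, variants:

====  ======  =================
J     pi_z    approx E[F]
====  ======  =================
9     0.10    7.30
25    0.06    3.27
100   0.03    1.57
====  ======  =================

``run_monte_carlo`` replays the full study for one design: per replicate it
simulates a dataset, fits the requested estimators (CUE from the five
standard starts), evaluates conventional and corrected Wald tests, and
aggregates median bias, IQR and rejection frequencies.  Medians and IQRs are
reported deliberately -- LIML and the CUE occasionally produce very large
outliers, which distort means but not quantiles -- and no trimming is
applied.  Replicates draw from independent substreams spawned from the
master seed, so aggregates are reproducible under any execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import inference as inf
from . import estimators as est
from .data import IVData
from .scores import GenotypeMatrix, unweighted_score

__all__ = [
    "SIGMA_V2", "SIGMA_UV", "SimulationDesign", "MonteCarloSummary",
    "generate_genotypes", "simulate_dataset", "run_monte_carlo",
    "standard_design", "standard_designs", "table_one",
]

#: first-stage composite error variance implied by the DGP (w + eps_x)
SIGMA_V2 = 2.0
#: covariance of the first-stage and outcome errors implied by the confounder
SIGMA_UV = 1.0

#: (pi_z per J) of the three standard designs; all give mu^2 = 56.70
STANDARD_PI = {9: 0.10, 25: 0.06, 100: 0.03}

_ALL_ESTIMATORS = ("ols", "tsls", "gmm2", "liml", "cue", "allele_score")


@dataclass(frozen=True)
class SimulationDesign:
    """Parameters of one simulation design."""

    n: int = 3000
    J: int = 9
    pi_z: float = 0.1
    maf: float = 0.3
    beta: float = 0.0
    reps: int = 10000
    seed: int = 0
    estimators: tuple = ("tsls", "liml", "cue", "allele_score")
    alpha: float = 0.05

    def __post_init__(self):
        if not 0.0 < self.maf < 1.0:
            raise ValueError("maf must lie in (0, 1)")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not np.isfinite(self.pi_z):
            raise ValueError("pi_z must be finite")
        unknown = set(self.estimators) - set(_ALL_ESTIMATORS)
        if unknown:
            raise ValueError(f"unknown estimators {sorted(unknown)}")

    @property
    def sigma_z2(self) -> float:
        return 2.0 * self.maf * (1.0 - self.maf)

    @property
    def mu2(self) -> float:
        """Concentration parameter implied by the design."""
        return inf.concentration_parameter(self.n, self.J, self.pi_z,
                                           self.maf, SIGMA_V2)

    def theoretical(self) -> dict:
        """Analytic constants: mu^2, approximate E[F], bias approximations."""
        out = {"mu2": self.mu2, "expected_f": inf.expected_f(self.mu2, self.J)}
        try:
            out["bias_2sls"] = inf.bias_2sls_approx(self.J, self.mu2,
                                                    SIGMA_UV, SIGMA_V2)
        except Exception:
            out["bias_2sls"] = float("nan")
        try:
            out["bias_liml"] = inf.bias_liml_approx(self.mu2, SIGMA_UV, SIGMA_V2)
        except Exception:
            out["bias_liml"] = float("nan")
        return out


def standard_design(J: int, reps: int = 10000, seed: int = 0,
                    **overrides) -> SimulationDesign:
    """One of the three standard designs (J in {9, 25, 100})."""
    if J not in STANDARD_PI:
        raise ValueError(f"standard designs have J in {sorted(STANDARD_PI)}")
    return replace(SimulationDesign(J=J, pi_z=STANDARD_PI[J],
                                    reps=reps, seed=seed), **overrides)


def standard_designs(reps: int = 10000, seed: int = 0, **overrides):
    """All three standard designs, with per-design decorrelated seeds."""
    return [standard_design(J, reps=reps, seed=seed + i, **overrides)
            for i, J in enumerate(sorted(STANDARD_PI))]


def generate_genotypes(n: int, J: int, maf: float,
                       rng: np.random.Generator) -> GenotypeMatrix:
    """Draw an n x J genotype matrix with i.i.d. Binomial(2, maf) entries.

    Sampling inverts a single uniform per entry against the cumulative
    genotype probabilities ((1-maf)^2, 2 maf (1-maf), maf^2), which is
    several times faster than a generic binomial sampler and bit-reproducible
    for a given generator state.
    """
    if not 0.0 <= maf <= 1.0:
        raise ValueError("maf must lie in [0, 1]")
    u = rng.random((n, J))
    p0 = (1.0 - maf) ** 2
    p01 = p0 + 2.0 * maf * (1.0 - maf)
    G = (u >= p0).view(np.int8) + (u >= p01).view(np.int8)
    return GenotypeMatrix(G.astype(np.int64), [f"v{j+1}" for j in range(J)])


def simulate_dataset(design: SimulationDesign,
                     rng: np.random.Generator) -> IVData:
    """One dataset from the DGP; returns it as an :class:`IVData`."""
    n, J = design.n, design.J
    G = generate_genotypes(n, J, design.maf, rng).G.astype(np.float64)
    w = rng.standard_normal(n)
    eps_x = rng.standard_normal(n)
    eps_y = rng.standard_normal(n)
    x = design.pi_z * G.sum(axis=1) + w + eps_x
    y = design.beta * x + w + eps_y
    return IVData(y, x, G)


@dataclass
class MonteCarloSummary:
    """Aggregated Monte Carlo results for one design."""

    design: SimulationDesign
    reps_completed: int
    mean_first_stage_f: float
    estimators: dict            # name -> {median, iqr, rejection_frequency:{kind: rf}}
    theoretical: dict
    failures: dict              # name -> count
    per_rep: pd.DataFrame | None = field(default=None, repr=False)
    fstats: np.ndarray | None = field(default=None, repr=False)

    @property
    def any_excess_failures(self) -> bool:
        """True when any estimator failed on more than 1% of replicates."""
        return any(c > 0.01 * self.design.reps for c in self.failures.values())

    def to_dict(self) -> dict:
        d = {"design": {k: (list(v) if isinstance(v, tuple) else v)
                        for k, v in vars(self.design).items()},
             "reps_completed": self.reps_completed,
             "mean_first_stage_f": self.mean_first_stage_f,
             "theoretical": self.theoretical,
             "estimators": self.estimators,
             "failures": self.failures}
        return d


_SE_KINDS = {"ols": ("conventional",),
             "tsls": ("conventional",),
             "gmm2": ("conventional",),
             "liml": ("conventional", "bekker"),
             "cue": ("conventional", "newey_windmeijer"),
             "allele_score": ("conventional",)}


def _fit_one(name: str, data: IVData):
    """Fit one estimator and return (beta, {kind: se}, extras)."""
    if name == "allele_score":
        score = data.Z_raw.sum(axis=1)
        sdata = IVData(data.y_raw, data.X_raw, score,
                       include_intercept=data.include_intercept)
        r = est.fit_2sls(sdata)
        return r, {"conventional": inf.conventional_se(r, sdata)}
    r = est.fit(data, name)
    out = {"conventional": inf.conventional_se(r, data)}
    if name == "liml":
        out["bekker"] = inf.bekker_se(r, data)
    elif name == "cue":
        out["newey_windmeijer"] = inf.nw_se(r, data)
    return r, out


def run_monte_carlo(design: SimulationDesign,
                    keep_reps: bool = False) -> MonteCarloSummary:
    """Run the full Monte Carlo study for one design.

    Per-replicate failures are recorded per estimator and excluded from that
    estimator's aggregates without aborting the run; ``any_excess_failures``
    flags runs where an estimator failed on more than 1% of replicates.
    """
    reps = design.reps
    children = np.random.SeedSequence(design.seed).spawn(reps)
    names = list(design.estimators)
    betas = {m: np.full(reps, np.nan) for m in names}
    ses = {m: {k: np.full(reps, np.nan) for k in _SE_KINDS[m]} for m in names}
    fstats = np.full(reps, np.nan)
    failures = {m: 0 for m in names}

    for r in range(reps):
        rng = np.random.default_rng(children[r])
        data = simulate_dataset(design, rng)
        fstats[r] = inf.first_stage_diagnostics(
            data, sigma_uv=SIGMA_UV, sigma_v2=SIGMA_V2).f_statistic
        for m in names:
            try:
                fit_res, se_map = _fit_one(m, data)
                betas[m][r] = fit_res.beta_hat[0]
                for kind, ir in se_map.items():
                    ses[m][kind][r] = ir.se[0]
            except Exception:
                failures[m] += 1

    crit = _two_sided_crit(design.alpha)
    summaries = {}
    for m in names:
        ok = np.isfinite(betas[m])
        b = betas[m][ok]
        entry = {"median": float(np.median(b)) if b.size else float("nan"),
                 "iqr": float(np.subtract(*np.percentile(b, [75, 25])))
                        if b.size else float("nan"),
                 "rejection_frequency": {}}
        for kind, s in ses[m].items():
            sk = s[ok]
            with np.errstate(invalid="ignore", divide="ignore"):
                rej = np.abs(b / sk) > crit
            entry["rejection_frequency"][kind] = float(np.mean(rej)) if b.size \
                else float("nan")
        summaries[m] = entry

    per_rep = None
    if keep_reps:
        rows = []
        for m in names:
            for kind in _SE_KINDS[m]:
                rows.append(pd.DataFrame({
                    "rep": np.arange(reps), "estimator": m, "se_kind": kind,
                    "beta_hat": betas[m], "se": ses[m][kind]}))
        per_rep = pd.concat(rows, ignore_index=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            per_rep["reject"] = (
                np.abs(per_rep["beta_hat"] / per_rep["se"]) > crit)

    return MonteCarloSummary(
        design=design, reps_completed=reps,
        mean_first_stage_f=float(np.nanmean(fstats)),
        estimators=summaries, theoretical=design.theoretical(),
        failures=failures, per_rep=per_rep,
        fstats=fstats if keep_reps else None)


def _two_sided_crit(alpha: float) -> float:
    # |beta/se| threshold equivalent to the chi-square(1) Wald test at alpha;
    # kept in one place so the rejection rule is identical everywhere
    from scipy import special
    return float(np.sqrt(2.0) * special.erfcinv(alpha))


_ROW_LABELS = [("tsls", "2SLS", "conventional", None),
               ("liml", "LIML", "conventional", "bias_liml"),
               ("liml", "Corrected LIML", "bekker", None),
               ("cue", "CUE", "conventional", None),
               ("cue", "Corrected CUE", "newey_windmeijer", None),
               ("allele_score", "Allele score IV", "conventional", None),
               ("gmm2", "Two-step GMM", "conventional", None),
               ("ols", "OLS", "conventional", None)]


def table_one(designs=None, keep_reps: bool = False):
    """Run a list of designs and lay the results out side by side with the
    theoretical columns (approximate bias) in the familiar
    Bias / Median / IQR / RF format.

    Returns ``(text, payload)`` where ``payload`` is the machine-readable
    twin of the rendered table (plus the per-design summaries).
    """
    if designs is None:
        designs = standard_designs()
    designs = list(designs)
    if not designs:
        return "", {"designs": []}
    summaries = [run_monte_carlo(d, keep_reps=keep_reps) for d in designs]

    lines = [f"{'k':>4}  {'Estimator':<16}{'Bias':>8}{'Median':>8}"
             f"{'IQR':>8}{'RF':>8}",
             "-" * 52]
    payload = {"designs": []}
    for s in summaries:
        th = s.theoretical
        first = True
        for key, label, kind, _ in _ROW_LABELS:
            if key not in s.estimators:
                continue
            e = s.estimators[key]
            corrected = kind in ("bekker", "newey_windmeijer")
            bias = ""
            if not corrected:
                if key == "tsls":
                    bias = f"{th['bias_2sls']:8.3f}"
                elif key == "liml":
                    bias = f"{th['bias_liml']:8.3f}"
            med = "" if corrected else f"{e['median']:8.3f}"
            iqr = "" if corrected else f"{e['iqr']:8.3f}"
            rf = e["rejection_frequency"].get(kind)
            rf_s = "" if rf is None else f"{rf:8.3f}"
            kcol = f"{s.design.J:>4}" if first else "    "
            lines.append(f"{kcol}  {label:<16}{bias:>8}{med:>8}{iqr:>8}{rf_s:>8}")
            first = False
        payload["designs"].append(s.to_dict())
    lines.append("-" * 52)
    lines.append(f"Note: mu^2 = {summaries[0].theoretical['mu2']:.2f}; "
                 "approximate E[F] = "
                 + ", ".join(f"{s.theoretical['expected_f']:.2f}" for s in summaries)
                 + "; empirical mean F = "
                 + ", ".join(f"{s.mean_first_stage_f:.2f}" for s in summaries))
    return "\n".join(lines), payload
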
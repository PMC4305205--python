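import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from manyweakiv import (
    IVData,
    cue_objective,
    fit_2sls,
    fit_cue,
    fit_gmm2,
    fit_liml,
    fit_ols,
    sequential_fit,
)
from manyweakiv.exceptions import DegenerateDesignError

import _oracles as orc
from conftest import dgp_instance, random_instance


# ---------------------------------------------------------------------------
# OLS
# ---------------------------------------------------------------------------

def test_ols_exact_linear_relation():
    x = np.arange(1.0, 11.0)
    d = IVData(2.0 * x, x, x)
    assert fit_ols(d).beta_hat[0] == pytest.approx(2.0, abs=1e-12)


def test_ols_centering_invariance():
    rng = np.random.default_rng(7)
    x = rng.standard_normal(50)
    y = 1.5 * x + rng.standard_normal(50)
    b1 = fit_ols(IVData(y, x, x)).beta_hat[0]
    b2 = fit_ols(IVData(y - y.mean(), x - x.mean(), x - x.mean(),
                        include_intercept=False)).beta_hat[0]
    assert b1 == pytest.approx(b2, rel=1e-12)


def test_ols_confounding_bias_matches_closed_form():
    # under the genotype DGP the OLS slope converges to
    # sigma_xu / sigma_x^2 = 1 / (J pi^2 sigma_z^2 + 2) ~ 0.4907
    d = dgp_instance(11, n=30000, J=9)
    expected = 1.0 / (9 * 0.01 * 0.42 + 2.0)
    assert fit_ols(d).beta_hat[0] == pytest.approx(expected, abs=0.02)


def test_ols_singular_design_raises():
    x = np.ones(10) * 3.0
    x2 = np.column_stack([np.arange(10.0), np.arange(10.0)])
    with pytest.raises(DegenerateDesignError):
        fit_ols(IVData(np.arange(10.0), x2, np.random.default_rng(0)
                       .standard_normal((10, 3))))


# ---------------------------------------------------------------------------
# 2SLS
# ---------------------------------------------------------------------------

def test_2sls_equals_ols_when_instruments_are_exposures():
    d = random_instance(1)
    same = IVData(d.y_raw, d.X_raw, d.X_raw)
    assert fit_2sls(same).beta_hat[0] == pytest.approx(
        fit_ols(same).beta_hat[0], rel=1e-12)


def test_2sls_matches_two_regression_oracle_on_toy(toy6):
    y, x, z = toy6
    d = IVData(y, x, z)
    b = fit_2sls(d).beta_hat[0]
    assert b == pytest.approx(orc.tsls_two_regressions(y, x, z[:, None]),
                              rel=1e-11)


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_2sls_matches_two_regression_oracle_random(seed):
    d = random_instance(seed, n=80, J=4)
    b = fit_2sls(d).beta_hat[0]
    assert b == pytest.approx(
        orc.tsls_two_regressions(d.y_raw, d.X_raw[:, 0], d.Z_raw), rel=1e-10)


def test_2sls_and_ols_cross_checked_against_statsmodels():
    import statsmodels.api as sm
    from statsmodels.sandbox.regression.gmm import IV2SLS

    d = random_instance(15, n=200, J=4)
    y, x, Z = d.y_raw, d.X_raw[:, 0], d.Z_raw
    exog = sm.add_constant(x)
    inst = sm.add_constant(Z)
    sm_iv = IV2SLS(y, exog, instrument=inst).fit()
    assert fit_2sls(d).beta_hat[0] == pytest.approx(sm_iv.params[1], rel=1e-9)
    sm_ols = sm.OLS(y, exog).fit()
    assert fit_ols(d).beta_hat[0] == pytest.approx(sm_ols.params[1], rel=1e-10)


# ---------------------------------------------------------------------------
# two-step GMM
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seed", [0, 1, 2])
def test_gmm2_matches_loop_oracle(seed):
    d = random_instance(seed, n=70, J=4)
    init = fit_2sls(d)
    b = fit_gmm2(d, init).beta_hat[0]
    assert b == pytest.approx(
        orc.gmm2_loop(d.y_raw, d.X_raw[:, 0], d.Z_raw, init.beta_hat[0]),
        rel=1e-9)


def test_gmm2_asymptotically_equivalent_to_2sls_homoskedastic():
    # strong instruments, homoskedastic errors: the two estimators share a
    # limiting distribution, so a single large-n draw should agree closely
    rng = np.random.default_rng(42)
    n = 50000
    Z = rng.standard_normal((n, 3))
    w = rng.standard_normal(n)
    x = Z @ np.array([1.0, 0.8, 0.6]) + w + rng.standard_normal(n)
    y = 0.5 * x + w + rng.standard_normal(n)
    d = IVData(y, x, Z)
    b2, bg = fit_2sls(d).beta_hat[0], fit_gmm2(d).beta_hat[0]
    se = np.sqrt(2.0 / d.XPX[0, 0])          # ~ conventional 2SLS SE
    assert abs(bg - b2) < 2 * se


def test_gmm2_consistent_under_heteroskedasticity():
    rng = np.random.default_rng(9)
    n = 100000
    z = rng.standard_normal((n, 1))
    x = 0.9 * z[:, 0] + rng.standard_normal(n)
    u = rng.standard_normal(n) * np.sqrt(0.2 + z[:, 0] ** 2)
    y = 0.5 * x + u
    z2 = np.column_stack([z[:, 0], z[:, 0] ** 2 - 1])
    d = IVData(y, x, z2)
    b2 = fit_2sls(d).beta_hat[0]
    bg = fit_gmm2(d).beta_hat[0]
    assert abs(bg - 0.5) < 0.01 and abs(b2 - 0.5) < 0.01
    assert bg != pytest.approx(b2, abs=1e-12)   # weighting actually differs


# ---------------------------------------------------------------------------
# CUE
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seed", [0, 1, 2])
def test_cue_objective_matches_loop_oracle(seed):
    d = random_instance(seed, n=50, J=3)
    for beta in (-1.0, 0.0, 0.4, 2.5):
        assert cue_objective([beta], d) == pytest.approx(
            orc.cue_objective_loop(beta, d.y_raw, d.X_raw[:, 0], d.Z_raw),
            rel=1e-8)


def test_cue_objective_zero_when_just_identified():
    d = random_instance(5, n=60, J=1)
    b = fit_2sls(d).beta_hat
    assert cue_objective(b, d) == pytest.approx(0.0, abs=1e-8)


def test_cue_zero_residual_boundary_is_flagged():
    x = np.arange(1.0, 31.0)
    rng = np.random.default_rng(0)
    Z = np.column_stack([x + rng.standard_normal(30) * 0.1,
                         rng.standard_normal(30)])
    d = IVData(3.0 * x, x, Z)           # y = 3x exactly -> zero residuals
    # the weight matrix vanishes at the exact coefficient ...
    assert np.allclose(d.omega([3.0]), 0.0)
    # ... and the declared pseudo-inverse policy yields a finite objective
    q = cue_objective([3.0], d)
    assert np.isfinite(q) and q == pytest.approx(0.0, abs=1e-8)


def test_cue_matches_grid_search_oracle():
    d = random_instance(8, n=200, J=5)
    r = fit_cue(d)
    grid = np.arange(-5.0, 5.0, 1e-4)
    # coarse-to-fine: evaluate the package objective on the dense grid
    vals = [cue_objective([b], d) for b in grid[::100]]
    b0 = grid[::100][int(np.argmin(vals))]
    fine = np.arange(b0 - 0.02, b0 + 0.02, 1e-4)
    vals = [cue_objective([b], d) for b in fine]
    assert r.beta_hat[0] == pytest.approx(fine[int(np.argmin(vals))], abs=1e-3)


def test_cue_equals_2sls_when_just_identified():
    d = random_instance(10, n=100, J=1)
    assert fit_cue(d).beta_hat[0] == pytest.approx(
        fit_2sls(d).beta_hat[0], abs=1e-6)


# ---------------------------------------------------------------------------
# LIML
# ---------------------------------------------------------------------------

def test_liml_just_identified_equals_2sls_with_unit_kappa():
    d = random_instance(12, n=90, J=1)
    r = fit_liml(d)
    assert r.liml_kappa == pytest.approx(1.0, abs=1e-10)
    assert r.beta_hat[0] == pytest.approx(fit_2sls(d).beta_hat[0], rel=1e-8)


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_liml_matches_ratio_minimization_oracle(seed):
    d = random_instance(seed, n=100, J=5)
    assert fit_liml(d).beta_hat[0] == pytest.approx(
        orc.liml_loop(d.y_raw, d.X_raw[:, 0], d.Z_raw), abs=1e-6)


def test_liml_equals_homoskedastic_cue():
    # replacing Omega(beta) by sigma^2(beta) Z'Z/n in the CUE criterion and
    # minimizing must reproduce LIML
    d = random_instance(21, n=120, J=4)

    def hom_objective(b):
        u = d.y - d.X @ np.array([b])
        s2 = (u @ u) / d.n
        g = d.moments([b])
        return d.n * g @ d.solve_zz(g) * d.n / s2

    r = minimize_scalar(hom_objective, bounds=(-20, 20), method="bounded",
                        options={"xatol": 1e-12})
    assert fit_liml(d).beta_hat[0] == pytest.approx(float(r.x), abs=1e-6)


# ---------------------------------------------------------------------------
# family-wide invariants
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seed", [0, 3, 6])
def test_just_identified_collapse(seed):
    d = random_instance(seed, n=80, J=1)
    ref = fit_2sls(d).beta_hat[0]
    for r in (fit_gmm2(d), fit_liml(d), fit_cue(d)):
        assert r.beta_hat[0] == pytest.approx(ref, rel=1e-8), r.estimator


@pytest.mark.parametrize("seed", [0, 1])
def test_instrument_rotation_invariance(seed):
    d = random_instance(seed, n=100, J=4)
    rng = np.random.default_rng(100 + seed)
    A = rng.standard_normal((4, 4)) + 4 * np.eye(4)
    d2 = d.with_instruments(d.Z_raw @ A)
    for f in (fit_2sls, fit_liml, fit_cue):
        b1, b2 = f(d).beta_hat[0], f(d2).beta_hat[0]
        assert b1 == pytest.approx(b2, rel=1e-7), f.__name__


def test_two_exposure_model_supported():
    rng = np.random.default_rng(3)
    n = 400
    Z = rng.standard_normal((n, 4))
    w = rng.standard_normal(n)
    X = Z @ np.array([[1.0, 0.2], [0.5, 0.9], [0.3, 0.4], [0.1, 0.8]])
    X = X + np.column_stack([w, w]) * 0.5 + rng.standard_normal((n, 2))
    y = X @ np.array([0.5, -0.3]) + w + rng.standard_normal(n)
    d = IVData(y, X, Z)
    for f in (fit_2sls, fit_liml, fit_gmm2, fit_cue):
        b = f(d).beta_hat
        assert b.shape == (2,)
        assert np.all(np.abs(b - np.array([0.5, -0.3])) < 0.5), f.__name__


# ---------------------------------------------------------------------------
# sequential sweep
# ---------------------------------------------------------------------------

def test_sequential_first_step_estimators_coincide():
    d = dgp_instance(31, n=800, J=5, pi_z=0.2)
    recs = sequential_fit(d, estimators=("tsls", "cue"))
    step1 = [r for r in recs if r["j"] == 1]
    assert step1[0]["beta"] == pytest.approx(step1[1]["beta"], abs=1e-6)


def test_sequential_matches_direct_subset_fits(toy6):
    y, x, z = toy6
    rng = np.random.default_rng(0)
    Z = np.column_stack([z, rng.standard_normal(6), rng.standard_normal(6)])
    d = IVData(y, x, Z)
    recs = sequential_fit(d, order=[0, 1, 2], estimators=("tsls",))
    for rec in recs:
        sub = d.subset_instruments(range(rec["j"]))
        assert rec["beta"] == pytest.approx(fit_2sls(sub).beta_hat[0], rel=1e-9)


def test_sequential_2sls_drifts_toward_ols_while_cue_stays():
    # many-weak-instrument bias: adding ever-weaker instruments pulls 2SLS
    # toward OLS while the CUE stays near the truth (aggregate over seeds)
    drift_2sls, drift_cue = [], []
    for seed in range(4):
        d = dgp_instance(200 + seed, n=1500, J=40, pi_z=0.05)
        recs = sequential_fit(d, estimators=("tsls", "cue"))
        first = {r["estimator"]: r["beta"] for r in recs if r["j"] == 5
                 and r["estimator"] == "tsls"}
        last = {r["estimator"]: r["beta"] for r in recs if r["j"] == 40}
        drift_2sls.append(last["tsls"])
        drift_cue.append(last["cue"])
    # truth is beta=0; OLS probability limit ~0.49
    assert np.mean(drift_2sls) > np.mean(drift_cue) + 0.05
    assert abs(np.mean(drift_cue)) < 0.25
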
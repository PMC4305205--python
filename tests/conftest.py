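import numpy as np
import pytest
from hypothesis import settings

from manyweakiv import IVData, standard_design, run_monte_carlo
from manyweakiv.simulate import SimulationDesign, simulate_dataset

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def toy6():
    """Six-observation instance with one instrument, solvable by hand."""
    y = np.array([1., 2., 3., 4., 5., 6.])
    x = np.array([1., 1., 2., 2., 3., 3.])
    z = np.array([0., 1., 0., 1., 1., 2.])
    return y, x, z


def random_instance(seed, n=60, J=3, rho=0.5, pi=0.6):
    """Small confounded IV instance with continuous instruments."""
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n, J))
    w = rng.standard_normal(n)
    x = Z @ np.full(J, pi) + w + rng.standard_normal(n)
    y = 0.5 * x + rho * w + rng.standard_normal(n)
    return IVData(y, x, Z)


def dgp_instance(seed, n=3000, J=9, pi_z=0.1, maf=0.3, beta=0.0):
    """One draw from the genotype-instrument DGP."""
    design = SimulationDesign(n=n, J=J, pi_z=pi_z, maf=maf, beta=beta,
                              reps=1, seed=seed)
    return simulate_dataset(design, np.random.default_rng(seed))


@pytest.fixture(scope="session")
def table1_mc():
    """Reduced-replication Monte Carlo runs of the three standard designs.

    Shared across the empirical acceptance checks; 2500/2500/2000 replicates
    keep the full suite within a desk-scale runtime while leaving Monte
    Carlo standard errors small enough for 3-sigma comparisons.
    """
    reps = {9: 2500, 25: 2500, 100: 2000}
    out = {}
    for i, J in enumerate((9, 25, 100)):
        d = standard_design(J, reps=reps[J], seed=2026 + i)
        out[J] = run_monte_carlo(d, keep_reps=True)
    return out
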
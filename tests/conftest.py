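import numpy as np
import pytest

from epmclock import AgeVector, MethylationMatrix, simulate_epm, simulate_mc


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def small_matrix():
    """3 sites x 4 individuals with hand-set values."""
    values = np.array(
        [
            [0.10, 0.20, 0.30, 0.40],
            [0.90, 0.80, 0.70, 0.60],
            [0.50, 0.55, 0.45, 0.52],
        ]
    )
    return MethylationMatrix(
        values=values,
        site_ids=["cg1", "cg2", "cg3"],
        individual_ids=["A", "B", "C", "D"],
    )


@pytest.fixture
def small_ages(small_matrix):
    return AgeVector(ages=np.array([10.0, 20.0, 30.0, 40.0]),
                     individual_ids=list(small_matrix.individual_ids))


@pytest.fixture
def mc_instance():
    """Moderate noisy constant-rate instance with known truth."""
    return simulate_mc(n=40, m=25, sigma=0.02, seed=11)


@pytest.fixture
def epm_instance():
    """Moderate noisy pacemaker instance with known truth."""
    return simulate_epm(n=40, m=25, sigma=0.02, seed=12)


def brute_force_time_minimizer(column, params):
    """Numeric 1-D minimizer of one column's RSS, independent of the closed form.

    Evaluates S_j(t) on a dense grid and reads the vertex off a quadratic
    least-squares fit to the evaluations (S_j is exactly quadratic in t, so
    the grid fit is unbiased and avoids the sqrt(eps) plateau of value-based
    line searches).
    """
    grid = np.linspace(-500.0, 500.0, 2001)
    resid = column[:, None] - (params.start_states[:, None]
                               + np.outer(params.rates, grid))
    s_vals = np.einsum("ij,ij->j", resid, resid)
    c0, c1, c2 = np.polynomial.polynomial.polyfit(grid, s_vals, 2)
    assert c2 > 0
    return -c1 / (2.0 * c2)


def random_instance(rng, n=None, m=None):
    """Small random instance with distinct ages and standard-normal levels."""
    n = n or int(rng.integers(1, 21))
    m = m or int(rng.integers(2, 16))
    t = rng.normal(50.0, 20.0, size=m)
    while np.ptp(t) == 0:  # pragma: no cover - measure zero
        t = rng.normal(50.0, 20.0, size=m)
    values = rng.standard_normal((n, m))
    matrix = MethylationMatrix(
        values=values,
        site_ids=[f"s{i}" for i in range(n)],
        individual_ids=[f"i{j}" for j in range(m)],
    )
    ages = AgeVector(ages=t, individual_ids=list(matrix.individual_ids))
    return matrix, ages
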
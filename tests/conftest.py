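"""Shared fixtures and independent brute-force oracles for the test suite.

The grid oracles fit the erf boundary models by exhaustive search over
boundary positions with the linear parameters (a, b) solved analytically
by ordinary least squares at each grid node.  They are deliberately
independent of the package's optimizer and serve as an upper bound on
the residual sum of squares a correct fit may report.
"""

import numpy as np
import pytest
from scipy.special import erf

from parquant import GroundTruth, gen_midsection_image


def _linear_ab(basis, y):
    """Solve y ~ a + b * basis by OLS; return (a, b, rss)."""
    X = np.column_stack([np.ones_like(basis), basis])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return coef[0], coef[1], float(resid @ resid)


def grid_oracle_single(x, y, n_grid=50):
    """Best rss of a + (b/2) erf(m (x - c)) over a (c, m) grid with
    analytic (a, b)."""
    best = np.inf
    span = x[-1] - x[0]
    for c in np.linspace(x[0], x[-1], n_grid):
        for m in np.geomspace(1.0, 500.0, n_grid):
            _, _, rss = _linear_ab(0.5 * erf(m * (x - c)), y)
            best = min(best, rss)
    return best


def grid_oracle_double(x, y, m, n_grid=50):
    """Best rss of the double-erf model over a (c1, c2) grid at fixed m
    with analytic (a, b)."""
    cs = np.linspace(0.0, 1.0, n_grid)
    best = np.inf
    for i, c1 in enumerate(cs):
        for c2 in cs[i + 1:]:
            basis = 0.5 * (erf(m * (x - c1)) - erf(m * (x - c2)))
            _, _, rss = _linear_ab(basis, y)
            best = min(best, rss)
    return best


@pytest.fixture
def noiseless_truth():
    return GroundTruth(seed=11)


@pytest.fixture
def midsection_embryo(noiseless_truth):
    """A noiseless midsection render shared across profile tests."""
    return gen_midsection_image(noiseless_truth, shape=(256, 256))
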
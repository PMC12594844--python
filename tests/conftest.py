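import numpy as np
import pytest

from biwrss import BIWParams, draw_rss, draw_srs

#: the four parameter configurations exercised throughout the suite,
#: in the order (alpha, lam1, lam2, lam3)
PARAM_SETS = (
    BIWParams(1.0, 0.5, 1.0, 1.0),
    BIWParams(0.5, 0.5, 0.5, 1.0),
    BIWParams(2.0, 2.0, 2.0, 0.5),
    BIWParams(1.5, 0.2, 0.8, 0.4),
)


@pytest.fixture(scope="session")
def params():
    """Reference parameter set (alpha=1, lam=(0.5, 1, 1))."""
    return PARAM_SETS[0]


@pytest.fixture(scope="session")
def srs_small(params):
    return draw_srs(params, 50, seed=101)


@pytest.fixture(scope="session")
def rss_small(params):
    return draw_rss(params, 3, 2, seed=102)


@pytest.fixture(scope="session")
def srs_big(params):
    return draw_srs(params, 100_000, seed=103)


def log_quad_nodes(lo=-14.0, hi=14.0, k=400):
    """Gauss-Legendre nodes/weights on a log grid of (0, inf)."""
    t, w = np.polynomial.legendre.leggauss(k)
    logx = 0.5 * (hi - lo) * t + 0.5 * (hi + lo)
    x = np.exp(logx)
    return x, w * 0.5 * (hi - lo) * x  # weight includes dx = x dlogx
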
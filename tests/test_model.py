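"""Distributional identities of the univariate and bivariate inverse Weibull."""

import numpy as np
import pytest

from biwrss import (
    BIWParams,
    Region,
    biw_cdf,
    biw_pdf,
    iw_cdf,
    iw_pdf,
    singular_mass,
)

from conftest import PARAM_SETS, log_quad_nodes


@pytest.mark.parametrize(
    "x, alpha, lam, expected",
    [
        (1.0, 2.0, 1.0, np.exp(-1.0)),
        (2.0, 1.0, 3.0, np.exp(-1.5)),
        (1e12, 1.0, 1.0, 1.0),
    ],
)
def test_iw_cdf_values(x, alpha, lam, expected):
    assert iw_cdf(x, alpha, lam) == pytest.approx(expected, rel=1e-12)


def test_iw_cdf_monotone_with_limits():
    x = np.linspace(0.01, 50, 500)
    F = iw_cdf(x, 1.5, 2.0)
    assert np.all(np.diff(F) > 0)
    assert iw_cdf(1e-8, 1.5, 2.0) < 1e-12
    assert iw_cdf(1e8, 1.5, 2.0) == pytest.approx(1.0)


def test_iw_domain_errors():
    with pytest.raises(ValueError):
        iw_cdf(-1.0, 1.0, 1.0)
    with pytest.raises(ValueError):
        iw_cdf(1.0, 0.0, 1.0)
    with pytest.raises(ValueError):
        iw_pdf(1.0, 1.0, 0.0)


def test_iw_pdf_normalises_and_matches_cdf_derivative():
    x, w = log_quad_nodes()
    assert iw_pdf(x, 1.5, 2.0) @ w == pytest.approx(1.0, abs=1e-8)
    assert iw_pdf(1.0, 1.0, 1.0) == pytest.approx(np.exp(-1.0))
    h = 1e-5
    fd = (iw_cdf(0.7 + h, 1.5, 2.0) - iw_cdf(0.7 - h, 1.5, 2.0)) / (2 * h)
    assert iw_pdf(0.7, 1.5, 2.0) == pytest.approx(fd, rel=1e-7)


class TestJointCdf:
    def test_diagonal_branch(self, params):
        for t in (0.3, 1.0, 4.0):
            assert biw_cdf(t, t, params) == pytest.approx(
                iw_cdf(t, params.alpha, params.lam123)
            )

    def test_independence_limit_factorises(self):
        p = BIWParams(1.3, 0.7, 1.2, 0.0)
        x, y = 0.8, 2.1
        assert biw_cdf(x, y, p) == pytest.approx(
            iw_cdf(x, p.alpha, p.lam1) * iw_cdf(y, p.alpha, p.lam2)
        )

    def test_hand_value(self):
        p = BIWParams(1.0, 0.5, 1.0, 1.0)
        assert biw_cdf(1.0, 2.0, p) == pytest.approx(np.exp(-1.5) * np.exp(-0.5))

    def test_swap_symmetry(self):
        p = BIWParams(1.2, 0.4, 0.9, 0.6)
        q = BIWParams(1.2, 0.9, 0.4, 0.6)
        assert biw_cdf(0.7, 1.9, p) == pytest.approx(biw_cdf(1.9, 0.7, q))

    @pytest.mark.parametrize("p", PARAM_SETS, ids=str)
    def test_marginal_limits(self, p):
        big = 1e14
        for t in (0.5, 1.5):
            assert biw_cdf(t, big, p) == pytest.approx(
                iw_cdf(t, p.alpha, p.lam13), rel=1e-6
            )
            assert biw_cdf(big, t, p) == pytest.approx(
                iw_cdf(t, p.alpha, p.lam23), rel=1e-6
            )


class TestJointPdf:
    def test_hand_value_lower_branch(self):
        p = BIWParams(1.0, 0.5, 1.0, 1.0)
        val, region = biw_pdf(1.0, 2.0, p)
        # lam13*lam2 * x^-2 * y^-2 * exp(-lam13/x - lam2/y) = 0.375 e^-2
        assert region is Region.X_LT_Y
        assert val == pytest.approx(0.375 * np.exp(-2.0), rel=1e-12)

    def test_swap_symmetry(self):
        p = BIWParams(1.4, 0.4, 0.9, 0.6)
        q = BIWParams(1.4, 0.9, 0.4, 0.6)
        v1, r1 = biw_pdf(0.6, 1.7, p)
        v2, r2 = biw_pdf(1.7, 0.6, q)
        assert v1 == pytest.approx(v2)
        assert (r1, r2) == (Region.X_LT_Y, Region.X_GT_Y)

    def test_matches_cdf_cross_derivative(self):
        rng = np.random.default_rng(42)
        for p in PARAM_SETS:
            for _ in range(10):
                x, y = np.exp(rng.uniform(-1.0, 1.5, size=2))
                if abs(x - y) < 0.05:
                    continue
                h = 1e-4
                fd = (
                    biw_cdf(x + h, y + h, p) - biw_cdf(x + h, y - h, p)
                    - biw_cdf(x - h, y + h, p) + biw_cdf(x - h, y - h, p)
                ) / (4 * h * h)
                val, _ = biw_pdf(x, y, p)
                assert val == pytest.approx(fd, rel=1e-5, abs=1e-10)

    @pytest.mark.parametrize("p", PARAM_SETS, ids=str)
    def test_total_mass_continuous_plus_singular(self, p):
        # off-diagonal branches integrated over their triangles in the
        # coordinates (t, y) with x = y * exp(-t); the diagonal branch is a
        # 1-D integral along {x = y}
        tt, tw = np.polynomial.legendre.leggauss(200)
        t_nodes, t_wts = 40.0 * (tt + 1), 40.0 * tw
        y, wy = log_quad_nodes(-30.0, 30.0, 400)
        cont = 0.0
        for t, wt in zip(t_nodes, t_wts):
            s = np.exp(-t)
            f_lt = np.array([biw_pdf(s * v, v, p)[0] for v in y])
            f_gt = np.array([biw_pdf(v, s * v, p)[0] for v in y])
            cont += wt * s * ((f_lt + f_gt) * y) @ wy
        diag = sum(w * biw_pdf(v, v, p)[0] for v, w in zip(y, wy))
        assert cont + diag == pytest.approx(1.0, abs=1e-4)
        assert diag == pytest.approx(singular_mass(p), abs=1e-5)

    def test_domain_errors(self, params):
        with pytest.raises(ValueError):
            biw_pdf(-1.0, 1.0, params)
        with pytest.raises(ValueError):
            biw_cdf(1.0, 0.0, params)


class TestSingularMass:
    def test_independence_gives_zero(self):
        assert singular_mass(BIWParams(1.0, 1.0, 1.0, 0.0)) == 0.0

    def test_comonotone_limit(self):
        p = BIWParams(1.0, 1e-12, 1e-12, 1.0)
        assert singular_mass(p) == pytest.approx(1.0)

    def test_reference_value(self):
        assert singular_mass(BIWParams(1.0, 0.5, 1.0, 1.0)) == pytest.approx(0.4)

    def test_monte_carlo_frequency(self, params, srs_big):
        p3 = singular_mass(params)
        n = srs_big.n
        se = np.sqrt(p3 * (1 - p3) / n)
        assert abs(srs_big.n3 / n - p3) < 3 * se
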
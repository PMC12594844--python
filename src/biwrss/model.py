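"""Densities and distribution functions of the bivariate inverse Weibull model.

The univariate inverse Weibull (IW) law has cdf F(x) = exp(-lam * x**-alpha).
The bivariate model BIW(alpha, lam1, lam2, lam3) is the Marshall-Olkin
max-construction X = max(U1, U3), Y = max(U2, U3) with U_k ~ IW(alpha, lam_k)
sharing the shape alpha.  Its joint cdf factorises piecewise,

    F(x, y) = F_IW(x; lam13) F_IW(y; lam2)   for x < y,
    F(x, y) = F_IW(x; lam1) F_IW(y; lam23)   for x > y,
    F(x, y) = F_IW(x; lam123)                for x = y,

and the density has two absolutely continuous branches plus a singular
component supported on the diagonal (common-shock ties), a density with
respect to the one-dimensional measure on {x = y}.

All densities are evaluated in log space internally: for small x the factor
x**(-alpha-1) overflows while the exponential underflows, and the log form
keeps the product finite.
"""

from __future__ import annotations

import enum

import numpy as np

from .params import BIWParams

__all__ = [
    "Region",
    "iw_cdf",
    "iw_pdf",
    "iw_logpdf",
    "biw_cdf",
    "biw_pdf",
    "biw_logpdf",
    "singular_mass",
]


class Region(enum.Enum):
    """Branch of the piecewise joint density a point (x, y) falls in."""

    X_LT_Y = "x<y"
    X_GT_Y = "x>y"
    X_EQ_Y = "x=y"


def _check_positive(name, value):
    arr = np.asarray(value, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError(f"{name} must be strictly positive and finite")
    return arr


def iw_cdf(x, alpha, lam):
    """Inverse Weibull cdf exp(-lam * x**-alpha).

    Parameters
    ----------
    x : array_like, > 0
    alpha : float, > 0
        Shape parameter.
    lam : float, >= 0
        Rate-like scale parameter; lam = 0 gives the point mass limit F = 1.
    """
    x = _check_positive("x", x)
    alpha = float(_check_positive("alpha", alpha))
    if lam < 0:
        raise ValueError("lam must be >= 0")
    return np.exp(-lam * x ** -alpha)


def iw_logpdf(x, alpha, lam):
    """Log-density of the inverse Weibull distribution."""
    x = _check_positive("x", x)
    alpha = float(_check_positive("alpha", alpha))
    lam = float(_check_positive("lam", lam))
    lx = np.log(x)
    return np.log(alpha) + np.log(lam) - (alpha + 1.0) * lx - lam * np.exp(-alpha * lx)


def iw_pdf(x, alpha, lam):
    """Inverse Weibull density alpha*lam*x**(-alpha-1)*exp(-lam*x**-alpha)."""
    return np.exp(iw_logpdf(x, alpha, lam))


def biw_cdf(x, y, params: BIWParams):
    """Joint cdf of the BIW model, F(x, y) = P(X <= x, Y <= y).

    Equals F_IW(x; lam1) F_IW(y; lam2) F_IW(min(x, y); lam3): the shock U3
    must fall below both coordinates.
    """
    x = _check_positive("x", x)
    y = _check_positive("y", y)
    z = np.minimum(x, y)
    return (
        iw_cdf(x, params.alpha, params.lam1)
        * iw_cdf(y, params.alpha, params.lam2)
        * iw_cdf(z, params.alpha, params.lam3)
    )


def _region(x, y) -> Region:
    if x < y:
        return Region.X_LT_Y
    if x > y:
        return Region.X_GT_Y
    return Region.X_EQ_Y


def biw_logpdf(x, y, params: BIWParams):
    """Log joint density of (X, Y) at a single point, with its Region.

    Returns
    -------
    (logpdf, region) : tuple of float and Region
        The x = y branch is the density of the singular component with
        respect to arc measure on the diagonal parameterised by x.
    """
    x = float(_check_positive("x", x))
    y = float(_check_positive("y", y))
    a = params.alpha
    la = np.log(a)
    lx, ly = np.log(x), np.log(y)
    u, v = np.exp(-a * lx), np.exp(-a * ly)
    region = _region(x, y)
    if region is Region.X_LT_Y:
        val = (
            np.log(params.lam13) + np.log(params.lam2) + 2 * la
            - (a + 1) * (lx + ly) - params.lam13 * u - params.lam2 * v
        )
    elif region is Region.X_GT_Y:
        val = (
            np.log(params.lam1) + np.log(params.lam23) + 2 * la
            - (a + 1) * (lx + ly) - params.lam1 * u - params.lam23 * v
        )
    else:
        if params.lam3 == 0.0:
            val = -np.inf
        else:
            val = np.log(params.lam3) + la - (a + 1) * lx - params.lam123 * u
    return float(val), region


def biw_pdf(x, y, params: BIWParams):
    """Joint density of (X, Y) at a single point, with its Region."""
    lp, region = biw_logpdf(x, y, params)
    return float(np.exp(lp)), region


def singular_mass(params: BIWParams) -> float:
    """P(X = Y) = lam3 / (lam1 + lam2 + lam3).

    On the latent exponential scale T_k = U_k**-alpha ~ Exp(lam_k), ties occur
    exactly when the shock T3 is the smallest of the three, an event of
    probability lam3 / lam123.
    """
    return params.lam3 / params.lam123
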
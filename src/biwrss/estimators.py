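"""Scikit-learn style estimators for fitting the BIW model.

:class:`BIWMaximumLikelihood` maximises the SRS or RSS log-likelihood by
Newton-Raphson on log parameters and reports Wald confidence intervals from
the inverse observed information.  :class:`BIWBayes` computes the conjugate
mixture-of-gammas posterior when the shape alpha is known and the expansion
is tractable, and otherwise samples the posterior by Metropolis-within-Gibbs.

Both follow the scikit-learn estimator contract (``get_params`` /
``set_params``, fitted attributes with trailing underscores, ``fit``
returning ``self``) so they compose with sklearn model-selection utilities.
``X`` may be an array of shape (n, 2) with columns (x, y), or a ready-made
:class:`~biwrss.sampling.SRSSample` / :class:`~biwrss.sampling.RSSSample`;
for array input an RSS design is declared by passing ``ranks`` and
``set_size`` to ``fit``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm
from sklearn.base import BaseEstimator

from ._newton import moment_init, newton_mle_batch
from .bayes import (
    GammaPriorSet,
    MCMCConfig,
    bayes_self_estimates,
    credible_interval,
    fit_bayes_mcmc,
    posterior_mixture,
)
from .likelihood import LikelihoodData, _loglik, data_from_sample
from .params import BIWParams
from .sampling import RSSSample, SRSSample, draw_srs

__all__ = [
    "FitResult",
    "BIWMaximumLikelihood",
    "BIWBayes",
    "asymptotic_ci",
    "fit_mle",
    "fit_bayes",
]


def asymptotic_ci(vcov, estimates, conf_level: float = 0.95) -> np.ndarray:
    """Wald intervals estimate +/- z_(gamma/2) * sqrt(v_kk), shape (4, 2)."""
    vcov = np.asarray(vcov, float)
    estimates = np.asarray(estimates, float)
    diag = np.diagonal(vcov)
    if np.any(diag < 0):
        raise ValueError(
            "variance-covariance matrix has negative diagonal entries; "
            "the evaluation point is not a local maximum"
        )
    if not 0 < conf_level < 1:
        raise ValueError("conf_level must be in (0, 1)")
    z = norm.ppf(1.0 - (1.0 - conf_level) / 2.0)
    half = z * np.sqrt(diag)
    return np.stack([estimates - half, estimates + half], axis=-1)


@dataclass
class FitResult:
    """Point estimates, uncertainty and diagnostics of one fit."""

    params: BIWParams
    vcov: np.ndarray | None
    intervals: np.ndarray | None
    loglik: float
    converged: bool
    n_iter: int
    gradient_norm: float
    conf_level: float
    flags: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "estimates": {
                    "alpha": self.params.alpha,
                    "lam1": self.params.lam1,
                    "lam2": self.params.lam2,
                    "lam3": self.params.lam3,
                },
                "vcov": None if self.vcov is None else self.vcov.ravel().tolist(),
                "intervals": None if self.intervals is None else self.intervals.tolist(),
                "loglik": self.loglik,
                "converged": bool(self.converged),
                "iterations": int(self.n_iter),
                "gradient_norm": self.gradient_norm,
                "conf_level": self.conf_level,
                "flags": list(self.flags),
            },
            indent=2,
        )


def _coerce_sample(X, ranks=None, set_size=None):
    if isinstance(X, (SRSSample, RSSSample)):
        return X
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("X must have shape (n, 2) with columns (x, y)")
    if ranks is None:
        return SRSSample.from_xy(X[:, 0], X[:, 1])
    ranks = np.asarray(ranks, dtype=int)
    if set_size is None:
        set_size = int(ranks.max())
    n = len(ranks)
    if n % set_size:
        raise ValueError("RSS input length must be a multiple of set_size")
    r = n // set_size
    from .sampling import compute_indicators

    d1, d2, d3 = compute_indicators(X[:, 0], X[:, 1])
    cycle = np.repeat(np.arange(1, r + 1), set_size)
    return RSSSample(X[:, 0], X[:, 1], d1, d2, d3, ranks, cycle, m=set_size, r=r)


class BIWMaximumLikelihood(BaseEstimator):
    """Maximum-likelihood fit of BIW(alpha, lam1, lam2, lam3).

    Parameters
    ----------
    conf_level : float, default 0.95
        Level of the Wald confidence intervals.
    init : BIWParams, array of 4, or None
        Starting values; by default a moment-style initialiser (shape from
        the log-spread of max(x, y), rates from event frequencies).
    tol : float, default 1e-6
        Newton convergence threshold on the largest parameter update.
    max_iter, max_halvings : int
        Iteration and step-halving budgets.

    Attributes
    ----------
    alpha_, lam1_, lam2_, lam3_ : float
    params_ : BIWParams
    vcov_ : ndarray (4, 4), inverse observed information, order
        (alpha, lam1, lam2, lam3)
    conf_int_ : ndarray (4, 2)
    loglik_, n_iter_, converged_, gradient_norm_ : diagnostics
    result_ : FitResult
    """

    def __init__(self, conf_level=0.95, init=None, tol=1e-6, max_iter=200,
                 max_halvings=30):
        self.conf_level = conf_level
        self.init = init
        self.tol = tol
        self.max_iter = max_iter
        self.max_halvings = max_halvings

    def fit(self, X, y=None, *, ranks=None, set_size=None):
        sample = _coerce_sample(X, ranks, set_size)
        if sample.n < 5:
            warnings.warn("fewer than 5 observations; the fit may be unstable")
        flags = []
        if sample.n1 == 0 or sample.n2 == 0:
            warnings.warn(
                "a non-tie event category is empty (n1 or n2 = 0); "
                "identifiability is weak"
            )
            flags.append("degenerate_counts")
        data = data_from_sample(sample)
        bdata = LikelihoodData(
            data.lx[None], data.ly[None], data.d1[None], data.d2[None],
            data.d3[None], data.w1[None], data.w2[None],
        )
        if self.init is None:
            theta0 = moment_init(bdata)
        elif isinstance(self.init, BIWParams):
            theta0 = self.init.as_array()[None]
        else:
            theta0 = np.asarray(self.init, float)[None]
        res = newton_mle_batch(
            theta0, bdata, tol=self.tol, max_iter=self.max_iter,
            max_halvings=self.max_halvings,
        )
        theta = res["theta"][0]
        self.alpha_, self.lam1_, self.lam2_, self.lam3_ = theta
        self.params_ = BIWParams.from_array(theta)
        self.vcov_ = res["vcov"][0]
        self.loglik_ = float(res["loglik"][0])
        self.converged_ = bool(res["converged"][0])
        self.n_iter_ = int(res["n_iter"][0])
        self.gradient_norm_ = float(res["grad_norm"][0])
        if res["singular"][0]:
            flags.append("singular_hessian")
        if not self.converged_:
            flags.append("not_converged")
        try:
            self.conf_int_ = asymptotic_ci(self.vcov_, theta, self.conf_level)
        except ValueError:
            self.conf_int_ = np.full((4, 2), np.nan)
            flags.append("indefinite_information")
        self.result_ = FitResult(
            params=self.params_, vcov=self.vcov_, intervals=self.conf_int_,
            loglik=self.loglik_, converged=self.converged_, n_iter=self.n_iter_,
            gradient_norm=self.gradient_norm_, conf_level=self.conf_level,
            flags=flags,
        )
        self._n_obs = sample.n
        return self

    def score(self, X, y=None, *, ranks=None, set_size=None) -> float:
        """Mean log-likelihood per observation under the fitted parameters."""
        sample = _coerce_sample(X, ranks, set_size)
        return float(_loglik(self.params_.as_array(), data_from_sample(sample))
                     / sample.n)

    def sample(self, n_samples: int, random_state=None) -> SRSSample:
        """Draw an SRS of n_samples pairs from the fitted distribution."""
        return draw_srs(self.params_, n_samples, seed=random_state)


class BIWBayes(BaseEstimator):
    """Bayesian fit of the BIW model with gamma priors on the rates.

    Parameters
    ----------
    prior : GammaPriorSet, preset name, or None (baseline preset).
    alpha : float or None
        If given, the shape is treated as known.
    method : {'auto', 'mixture', 'mcmc'}
        'mixture' requires a known alpha and a tractable expansion; 'auto'
        picks the mixture when possible and falls back to MCMC.
    alpha_prior : (shape, rate) gamma prior on alpha for the MCMC route.
    n_iter, burn_in : MCMC chain length and burn-in.
    conf_level : credible-interval level.
    random_state : seed for the sampler.

    Attributes
    ----------
    alpha_, lam1_, lam2_, lam3_, params_ : SELF (posterior-mean) estimates.
    conf_int_ : ndarray (4, 2) equal-tailed credible intervals (MCMC route;
        NaN rows for fixed alpha / mixture route).
    mixture_ : PosteriorMixture or None
    chain_ : MCMCChain or None
    """

    def __init__(self, prior=None, alpha=None, method="auto",
                 alpha_prior=(2.0, 1.0), n_iter=10_000, burn_in=2_000,
                 conf_level=0.95, random_state=None, max_components=10**6):
        self.prior = prior
        self.alpha = alpha
        self.method = method
        self.alpha_prior = alpha_prior
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.conf_level = conf_level
        self.random_state = random_state
        self.max_components = max_components

    def _prior(self) -> GammaPriorSet:
        if self.prior is None:
            return GammaPriorSet.baseline()
        if isinstance(self.prior, str):
            return GammaPriorSet.preset(self.prior)
        return self.prior

    def fit(self, X, y=None, *, ranks=None, set_size=None):
        sample = _coerce_sample(X, ranks, set_size)
        prior = self._prior()
        self.mixture_ = None
        self.chain_ = None
        method = self.method
        if method == "mixture" and self.alpha is None:
            raise ValueError("the mixture route requires a known alpha")
        if method == "auto":
            use_mixture = self.alpha is not None
            if use_mixture:
                try:
                    self.mixture_ = posterior_mixture(
                        sample, prior, self.alpha,
                        max_components=self.max_components,
                    )
                except ValueError:
                    use_mixture = False
            method = "mixture" if use_mixture else "mcmc"
        if method == "mixture":
            if self.mixture_ is None:
                self.mixture_ = posterior_mixture(
                    sample, prior, self.alpha, max_components=self.max_components
                )
            lam = bayes_self_estimates(self.mixture_)
            theta = np.array([self.alpha, *lam])
            self.conf_int_ = np.full((4, 2), np.nan)
        else:
            cfg = MCMCConfig(n_iter=self.n_iter, burn_in=self.burn_in)
            self.chain_, params, intervals = fit_bayes_mcmc(
                sample, prior, alpha_prior=self.alpha_prior,
                known_alpha=self.alpha, config=cfg,
                seed=self.random_state, level=self.conf_level,
            )
            theta = params.as_array()
            self.conf_int_ = intervals
        self.alpha_, self.lam1_, self.lam2_, self.lam3_ = theta
        self.params_ = BIWParams.from_array(theta)
        self.method_ = method
        return self

    def score(self, X, y=None, *, ranks=None, set_size=None) -> float:
        """Mean log-likelihood per observation at the posterior mean."""
        sample = _coerce_sample(X, ranks, set_size)
        return float(_loglik(self.params_.as_array(), data_from_sample(sample))
                     / sample.n)

    def credible_interval(self, level: float | None = None) -> np.ndarray:
        if self.chain_ is None:
            raise ValueError("credible intervals require the MCMC route")
        return credible_interval(self.chain_, level or self.conf_level)


def fit_mle(sample, init=None, conf_level: float = 0.95) -> FitResult:
    """Functional wrapper over :class:`BIWMaximumLikelihood`."""
    est = BIWMaximumLikelihood(conf_level=conf_level, init=init).fit(sample)
    return est.result_


def fit_bayes(sample, prior=None, alpha=None, seed=None, **kwargs):
    """Functional wrapper over :class:`BIWBayes`; returns the fitted estimator."""
    return BIWBayes(prior=prior, alpha=alpha, random_state=seed, **kwargs).fit(sample)
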
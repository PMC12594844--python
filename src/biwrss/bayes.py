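"""Conjugate-gamma Bayesian estimation for the BIW model.

With the shape alpha known, independent Gamma(a_i, b_i) priors on the rates
(lam1, lam2, lam3) are conjugate to the BIW likelihood once the mixed-rate
powers are expanded binomially:

    (lam1 + lam3)^N1 = sum_k C(N1, k) lam1^k lam3^(N1-k),
    (lam2 + lam3)^N2 = sum_s C(N2, s) lam2^s lam3^(N2-s),

and, for a ranked-set sample, each factor (1 - e^(-lam13 x^-alpha))^(m-i)
expands into signed exponential terms.  The posterior is then an exact
finite mixture of products of three gamma densities with signed weights;
the posterior mean under squared-error loss (SELF) is a weighted sum of
component shape/rate ratios.  Signed weights are handled in log space.

When alpha is unknown (or the expansion is too large) a seeded
Metropolis-within-Gibbs sampler with Gaussian random walks on the log
parameters targets prior x likelihood directly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from .likelihood import LikelihoodData, _loglik, data_from_sample
from .params import BIWParams
from .sampling import RSSSample

__all__ = [
    "GammaPriorSet",
    "PosteriorMixture",
    "MCMCConfig",
    "MCMCChain",
    "posterior_mixture",
    "bayes_self_estimates",
    "fit_bayes_mcmc",
    "credible_interval",
]


@dataclass(frozen=True)
class GammaPriorSet:
    """Independent Gamma(shape a_i, rate b_i) priors on (lam1, lam2, lam3)."""

    a1: float = 2.0
    a2: float = 2.0
    a3: float = 2.0
    b1: float = 1.0
    b2: float = 1.0
    b3: float = 1.0

    def __post_init__(self):
        if min(self.a1, self.a2, self.a3, self.b1, self.b2, self.b3) <= 0:
            raise ValueError("all prior hyperparameters must be positive")

    @classmethod
    def baseline(cls) -> "GammaPriorSet":
        """Moderately informative preset: shapes 2, common rate 1."""
        return cls(2.0, 2.0, 2.0, 1.0, 1.0, 1.0)

    @classmethod
    def noninformative(cls) -> "GammaPriorSet":
        """Diffuse preset: shapes 1, common rate 0.5."""
        return cls(1.0, 1.0, 1.0, 0.5, 0.5, 0.5)

    @classmethod
    def alternative(cls) -> "GammaPriorSet":
        """Alternative moderately informative preset (shape c=2, rate d=1)."""
        return cls(2.0, 2.0, 2.0, 1.0, 1.0, 1.0)

    @classmethod
    def preset(cls, name: str) -> "GammaPriorSet":
        try:
            return getattr(cls, name)()
        except AttributeError:
            raise ValueError(f"unknown prior preset {name!r}") from None

    @property
    def shapes(self) -> np.ndarray:
        return np.array([self.a1, self.a2, self.a3])

    @property
    def rates(self) -> np.ndarray:
        return np.array([self.b1, self.b2, self.b3])


@dataclass
class PosteriorMixture:
    """Signed mixture of products of gamma densities for (lam1, lam2, lam3).

    ``weights`` are normalised (sum to 1, possibly signed), ``shapes`` and
    ``rates`` have one row per component and one column per rate parameter.
    """

    weights: np.ndarray
    shapes: np.ndarray
    rates: np.ndarray
    alpha: float

    @property
    def n_components(self) -> int:
        return len(self.weights)

    def mean(self) -> np.ndarray:
        """Posterior mean of (lam1, lam2, lam3) under squared-error loss."""
        return self.weights @ (self.shapes / self.rates)

    def pdf(self, lam1, lam2, lam3):
        """Posterior density at (lam1, lam2, lam3) (scalar or broadcastable)."""
        from scipy.stats import gamma as gamma_dist

        lam = np.stack(
            np.broadcast_arrays(
                np.asarray(lam1, float), np.asarray(lam2, float), np.asarray(lam3, float)
            ),
            axis=-1,
        )[..., None, :]
        comp = gamma_dist.pdf(lam, self.shapes, scale=1.0 / self.rates).prod(axis=-1)
        return comp @ self.weights


def _mixture_capacity_rss(sample: RSSSample, max_components: int) -> int:
    n_comp = (sample.n1 + 1) * (sample.n2 + 1)
    for rank in sample.rank:
        n_comp *= sample.m - int(rank) + 1
        if n_comp > max_components:
            raise ValueError(
                f"posterior mixture would exceed {max_components} components; "
                "use the MCMC route instead"
            )
    return n_comp


def posterior_mixture(
    sample,
    prior: GammaPriorSet,
    alpha: float,
    max_components: int = 10**6,
) -> PosteriorMixture:
    """Exact mixture-of-gammas posterior of (lam1, lam2, lam3), alpha known.

    For an SRS all weights are positive and there are (n1+1)(n2+1)
    components; for an RSS the per-observation expansion of the ranked
    factor (1 - F_X)^(m-i) contributes alternating signs and the component
    count is capacity-guarded.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    is_rss = isinstance(sample, RSSSample)
    x = np.asarray(sample.x, float)
    y = np.asarray(sample.y, float)
    d1 = np.asarray(sample.delta1, float)
    d2 = np.asarray(sample.delta2, float)
    d3 = np.asarray(sample.delta3, float)
    n1, n2, n3 = sample.n1, sample.n2, sample.n3
    ntot = n1 + n2 + n3
    u = x ** -alpha if len(x) else np.zeros(0)
    v = y ** -alpha if len(y) else np.zeros(0)
    z1 = float((d1 * v).sum())
    z2 = float((d2 * u).sum())
    z3 = float((d2 * v).sum())
    z5 = float((d3 * u).sum())
    if is_rss:
        _mixture_capacity_rss(sample, max_components)
        w1 = sample.rank.astype(float) - 1.0
        z4 = float(((d1 + w1) * u).sum())
        # one binomial index l_ij in 0..(m - i) per observation
        l_ranges = [range(sample.m - int(rank) + 1) for rank in sample.rank]
        l_grid = np.array(list(itertools.product(*l_ranges)), dtype=float)
        l_extra = l_grid @ u                      # adds to the lam13 rate
        l_sign = 1.0 - 2.0 * (l_grid.sum(axis=1) % 2)
        mchoose = np.array([sample.m - int(rank) for rank in sample.rank], float)
        l_logbin = (
            gammaln(mchoose + 1.0)
            - gammaln(l_grid + 1.0)
            - gammaln(mchoose - l_grid + 1.0)
        ).sum(axis=1)
    else:
        if (n1 + 1) * (n2 + 1) > max_components:
            raise ValueError(
                f"posterior mixture would exceed {max_components} components; "
                "use the MCMC route instead"
            )
        z4 = float((d1 * u).sum())
        l_extra = np.zeros(1)
        l_sign = np.ones(1)
        l_logbin = np.zeros(1)

    k = np.arange(n1 + 1.0)
    s_ = np.arange(n2 + 1.0)
    kk, ss, ll_ = np.meshgrid(k, s_, np.arange(len(l_extra)), indexing="ij")
    kk, ss, ll_ = kk.ravel(), ss.ravel(), ll_.ravel().astype(int)

    t1 = prior.b1 + z2 + z4 + z5 + l_extra[ll_]
    t2 = prior.b2 + z1 + z3 + z5
    t3 = prior.b3 + z3 + z4 + z5 + l_extra[ll_]
    a1k = prior.a1 + n2 + kk
    a2s = prior.a2 + n1 + ss
    a3ks = prior.a3 + ntot - kk - ss
    log_c = (
        gammaln(n1 + 1.0) - gammaln(kk + 1.0) - gammaln(n1 - kk + 1.0)
        + gammaln(n2 + 1.0) - gammaln(ss + 1.0) - gammaln(n2 - ss + 1.0)
        + l_logbin[ll_]
        + gammaln(a1k) - a1k * np.log(t1)
        + gammaln(a2s) - a2s * np.log(t2)
        + gammaln(a3ks) - a3ks * np.log(t3)
    )
    sign = l_sign[ll_]
    log_norm, norm_sign = logsumexp(log_c, b=sign, return_sign=True)
    weights = sign * norm_sign * np.exp(log_c - log_norm)
    shapes = np.stack([a1k, a2s, a3ks], axis=1)
    rates = np.stack([t1, np.full_like(t1, t2), t3], axis=1)
    return PosteriorMixture(weights, shapes, rates, alpha=float(alpha))


def bayes_self_estimates(mixture: PosteriorMixture) -> np.ndarray:
    """SELF (posterior-mean) estimates of (lam1, lam2, lam3)."""
    return mixture.mean()


@dataclass
class MCMCConfig:
    """Settings for the Metropolis-within-Gibbs sampler."""

    n_iter: int = 10_000
    burn_in: int = 2_000
    proposal_scale: float = 0.3
    adapt: bool = True
    target_accept: float = 0.3
    adapt_window: int = 50


@dataclass
class MCMCChain:
    """Post-burn-in draws of (alpha, lam1, lam2, lam3) with diagnostics."""

    draws: np.ndarray
    burn_in: int
    accept_rates: np.ndarray
    seed: object = None
    warnings: list = field(default_factory=list)


def _log_target(phi, data: LikelihoodData, prior: GammaPriorSet, alpha_prior):
    """Unnormalised log posterior on the log-parameter scale (with Jacobian)."""
    theta = np.exp(phi)
    ll = _loglik(theta, data)
    pa = prior.shapes
    pb = prior.rates
    lp = (pa * phi[..., 1:4]).sum(axis=-1) - (pb * theta[..., 1:4]).sum(axis=-1)
    if alpha_prior is not None:
        aa, ba = alpha_prior
        lp = lp + aa * phi[..., 0] - ba * theta[..., 0]
    return ll + lp


def mcmc_batch(
    data: LikelihoodData,
    prior: GammaPriorSet,
    theta0: np.ndarray,
    *,
    alpha_prior=(2.0, 1.0),
    known_alpha: float | None = None,
    config: MCMCConfig | None = None,
    rng: np.random.Generator,
    keep_draws: bool = True,
):
    """Run one Metropolis-within-Gibbs chain per batch row.

    Returns (posterior_means (..., 4), draws or None, accept_rates (..., 4)).
    With ``known_alpha`` set, the alpha block is frozen at that value.
    """
    cfg = config or MCMCConfig()
    theta0 = np.asarray(theta0, float)
    batch = theta0.shape[:-1]
    phi = np.log(theta0).copy()
    if known_alpha is not None:
        phi[..., 0] = np.log(known_alpha)
        ap = None
    else:
        ap = alpha_prior
    blocks = [1, 2, 3] if known_alpha is not None else [0, 1, 2, 3]
    scales = np.full(batch + (4,), cfg.proposal_scale)
    cur = _log_target(phi, data, prior, ap)
    kept = cfg.n_iter - cfg.burn_in
    if kept < 1:
        raise ValueError("n_iter must exceed burn_in")
    draws = np.empty(batch + (kept, 4)) if keep_draws else None
    mean_acc = np.zeros(batch + (4,))
    acc_count = np.zeros(batch + (4,))
    win_count = np.zeros(batch + (4,))

    for it in range(cfg.n_iter):
        for p in blocks:
            prop = phi.copy()
            prop[..., p] = phi[..., p] + scales[..., p] * rng.standard_normal(batch)
            new = _log_target(prop, data, prior, ap)
            logu = np.log(rng.random(batch))
            accept = np.isfinite(new) & (new - cur > logu)
            phi[..., p] = np.where(accept, prop[..., p], phi[..., p])
            cur = np.where(accept, new, cur)
            win_count[..., p] += accept
            if it >= cfg.burn_in:
                acc_count[..., p] += accept
        if cfg.adapt and it < cfg.burn_in and (it + 1) % cfg.adapt_window == 0:
            rate = win_count / cfg.adapt_window
            scales *= np.exp(rate - cfg.target_accept)
            win_count[:] = 0.0
        if it >= cfg.burn_in:
            k = it - cfg.burn_in
            if keep_draws:
                draws[..., k, :] = np.exp(phi)
            else:
                mean_acc += np.exp(phi)
    accept_rates = acc_count / kept
    means = draws.mean(axis=-2) if keep_draws else mean_acc / kept
    return means, draws, accept_rates


def fit_bayes_mcmc(
    sample,
    prior: GammaPriorSet | None = None,
    *,
    alpha_prior=(2.0, 1.0),
    known_alpha: float | None = None,
    config: MCMCConfig | None = None,
    seed=None,
    level: float = 0.95,
):
    """Posterior sampling for one sample; returns (chain, estimates, intervals).

    ``estimates`` are posterior means (SELF); ``intervals`` are equal-tailed
    credible intervals at ``level`` from the post-burn-in draws.  Fully
    reproducible under a fixed seed.
    """
    prior = prior or GammaPriorSet.baseline()
    cfg = config or MCMCConfig()
    rng = np.random.default_rng(seed)
    data = data_from_sample(sample)
    data2 = LikelihoodData(
        data.lx[None], data.ly[None], data.d1[None], data.d2[None], data.d3[None],
        data.w1[None], data.w2[None],
    )
    from ._newton import moment_init

    theta0 = moment_init(data2)
    if known_alpha is not None:
        theta0[..., 0] = known_alpha
    means, draws, acc = mcmc_batch(
        data2, prior, theta0,
        alpha_prior=alpha_prior, known_alpha=known_alpha,
        config=cfg, rng=rng, keep_draws=True,
    )
    chain = MCMCChain(draws[0], burn_in=cfg.burn_in, accept_rates=acc[0], seed=seed)
    active = [1, 2, 3] if known_alpha is not None else [0, 1, 2, 3]
    if np.any((acc[0][active] < 0.1) | (acc[0][active] > 0.6)):
        chain.warnings.append("acceptance rate outside [0.1, 0.6]")
    est = means[0]
    if known_alpha is not None:
        est = est.copy()
        est[0] = known_alpha
    intervals = credible_interval(chain, level)
    return chain, BIWParams.from_array(est), intervals


def credible_interval(chain: MCMCChain, level: float = 0.95) -> np.ndarray:
    """Equal-tailed credible intervals, shape (4, 2), from chain quantiles."""
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    draws = chain.draws
    if draws.shape[0] < 100:
        raise ValueError("need at least 100 post-burn-in draws")
    lo = (1.0 - level) / 2.0
    return np.quantile(draws, [lo, 1.0 - lo], axis=0).T
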
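"""Bayesian estimation: the closed-form / quadrature / MCMC triangle."""

import numpy as np
import pytest

from biwrss import (
    BIWBayes,
    BIWParams,
    GammaPriorSet,
    MCMCChain,
    MCMCConfig,
    SRSSample,
    bayes_self_estimates,
    credible_interval,
    draw_rss,
    draw_srs,
    fit_bayes_mcmc,
    posterior_mixture,
)
from biwrss.likelihood import _loglik, data_from_sample

from conftest import log_quad_nodes


@pytest.fixture(scope="module")
def prior():
    return GammaPriorSet.baseline()


def quadrature_posterior_means(sample, prior, alpha, k=80, hi=40.0):
    """Independent oracle: 3-D log-grid quadrature of likelihood x prior."""
    t, w = np.polynomial.legendre.leggauss(k)
    lo_l, hi_l = np.log(1e-4), np.log(hi)
    lam = np.exp(0.5 * (hi_l - lo_l) * t + 0.5 * (hi_l + lo_l))
    wl = w * 0.5 * (hi_l - lo_l) * lam
    L1, L2, L3 = np.meshgrid(lam, lam, lam, indexing="ij")
    W = wl[:, None, None] * wl[None, :, None] * wl[None, None, :]
    th = np.stack(
        [np.full(L1.size, alpha), L1.ravel(), L2.ravel(), L3.ravel()], axis=-1
    )
    data = data_from_sample(sample)
    lp = _loglik(th, data)
    lp = lp + (
        (prior.shapes - 1) * np.log(th[:, 1:4]) - prior.rates * th[:, 1:4]
    ).sum(axis=-1)
    lp -= lp.max()
    post = np.exp(lp).reshape(L1.shape)
    Z = (post * W).sum()
    return np.array([(post * W * L).sum() / Z for L in (L1, L2, L3)])


class TestPosteriorMixture:
    def test_empty_sample_returns_prior(self, prior):
        empty = SRSSample(*(np.empty(0),) * 5)
        mix = posterior_mixture(empty, prior, alpha=1.0)
        assert mix.n_components == 1
        np.testing.assert_allclose(mix.weights, [1.0])
        np.testing.assert_allclose(
            bayes_self_estimates(mix), prior.shapes / prior.rates
        )

    @pytest.mark.parametrize("seed,alpha", [(11, 1.0), (12, 1.5)])
    def test_srs_mixture_integrates_to_one(self, prior, seed, alpha):
        p = BIWParams(alpha, 0.5, 1.0, 1.0)
        sample = draw_srs(p, 3, seed=seed)
        mix = posterior_mixture(sample, prior, alpha=alpha)
        lam, wl = log_quad_nodes(lo=np.log(1e-4), hi=np.log(40.0), k=80)
        L1, L2, L3 = np.meshgrid(lam, lam, lam, indexing="ij")
        W = wl[:, None, None] * wl[None, :, None] * wl[None, None, :]
        assert (mix.pdf(L1, L2, L3) * W).sum() == pytest.approx(1.0, abs=1e-4)

    def test_rss_mixture_integrates_to_one(self, prior):
        p = BIWParams(1.0, 0.5, 1.0, 1.0)
        sample = draw_rss(p, 2, 2, seed=13)
        mix = posterior_mixture(sample, prior, alpha=1.0)
        lam, wl = log_quad_nodes(lo=np.log(1e-4), hi=np.log(40.0), k=80)
        L1, L2, L3 = np.meshgrid(lam, lam, lam, indexing="ij")
        W = wl[:, None, None] * wl[None, :, None] * wl[None, None, :]
        assert (mix.pdf(L1, L2, L3) * W).sum() == pytest.approx(1.0, abs=1e-4)

    @pytest.mark.parametrize("design", ["srs", "rss"])
    def test_self_estimates_match_quadrature(self, prior, design):
        p = BIWParams(1.0, 0.5, 1.0, 1.0)
        sample = (
            draw_srs(p, 3, seed=14) if design == "srs" else draw_rss(p, 2, 2, seed=15)
        )
        mix = posterior_mixture(sample, prior, alpha=1.0)
        got = bayes_self_estimates(mix)
        want = quadrature_posterior_means(sample, prior, 1.0)
        np.testing.assert_allclose(got, want, rtol=1e-3)

    def test_matches_importance_sampling(self, prior):
        p = BIWParams(1.0, 0.5, 1.0, 1.0)
        sample = draw_srs(p, 3, seed=16)
        mix = posterior_mixture(sample, prior, alpha=1.0)
        rng = np.random.default_rng(17)
        draws = rng.gamma(
            np.broadcast_to(prior.shapes, (200_000, 3)),
            1.0 / prior.rates,
        )
        th = np.column_stack([np.ones(len(draws)), draws])
        lw = _loglik(th, data_from_sample(sample))
        lw -= lw.max()
        w = np.exp(lw)
        est_is = (w[:, None] * draws).sum(0) / w.sum()
        ess = w.sum() ** 2 / (w**2).sum()
        se = np.sqrt(np.average((draws - est_is) ** 2, axis=0, weights=w) / ess)
        np.testing.assert_array_less(np.abs(bayes_self_estimates(mix) - est_is), 3 * se)

    def test_dominating_prior_limit(self):
        # as b -> inf with a/b = mu fixed the posterior mean goes to mu
        p = BIWParams(1.0, 0.5, 1.0, 1.0)
        sample = draw_srs(p, 3, seed=18)
        mu = np.array([0.7, 1.3, 0.9])
        b = 1e6
        prior = GammaPriorSet(*(mu * b), b, b, b)
        mix = posterior_mixture(sample, prior, alpha=1.0)
        np.testing.assert_allclose(bayes_self_estimates(mix), mu, rtol=1e-3)

    def test_capacity_guard(self, prior):
        p = BIWParams(1.0, 0.5, 1.0, 1.0)
        big = draw_rss(p, 12, 2, seed=19)
        with pytest.raises(ValueError, match="MCMC"):
            posterior_mixture(big, prior, alpha=1.0, max_components=10_000)


class TestMCMC:
    def test_seed_reproducibility(self, prior, params):
        sample = draw_srs(params, 20, seed=20)
        cfg = MCMCConfig(n_iter=600, burn_in=200)
        c1, e1, _ = fit_bayes_mcmc(sample, prior, config=cfg, seed=42)
        c2, e2, _ = fit_bayes_mcmc(sample, prior, config=cfg, seed=42)
        np.testing.assert_array_equal(c1.draws, c2.draws)
        assert e1.as_array() == pytest.approx(e2.as_array())

    def test_known_alpha_matches_closed_form(self, prior):
        p = BIWParams(1.0, 0.5, 1.0, 1.0)
        sample = draw_srs(p, 4, seed=21)
        mix_mean = bayes_self_estimates(posterior_mixture(sample, prior, alpha=1.0))
        cfg = MCMCConfig(n_iter=30_000, burn_in=5_000)
        chain, est, _ = fit_bayes_mcmc(
            sample, prior, known_alpha=1.0, config=cfg, seed=22
        )
        draws = chain.draws[:, 1:]
        # batched-means MC standard error (lag correlation folded in crudely)
        nb = 50
        bm = draws[: (len(draws) // nb) * nb].reshape(nb, -1, 3).mean(axis=1)
        se = bm.std(axis=0, ddof=1) / np.sqrt(nb)
        np.testing.assert_array_less(np.abs(est.as_array()[1:] - mix_mean), 4 * se)

    def test_credible_interval_calibration_smoke(self, params):
        # posterior intervals should usually cover the truth on mid-size data
        hits = 0
        reps = 20
        cfg = MCMCConfig(n_iter=1_500, burn_in=500)
        for k in range(reps):
            sample = draw_srs(params, 150, seed=900 + k)
            _, _, ci = fit_bayes_mcmc(sample, config=cfg, seed=k)
            inside = (ci[:, 0] <= params.as_array()) & (
                params.as_array() <= ci[:, 1]
            )
            hits += int(inside.all())
        assert hits >= reps // 2

    def test_estimator_api_mcmc_route(self, params):
        sample = draw_srs(params, 30, seed=23)
        est = BIWBayes(n_iter=800, burn_in=300, random_state=7).fit(sample)
        assert est.method_ == "mcmc"
        assert est.chain_.draws.shape == (500, 4)
        ci = est.credible_interval()
        assert np.all(ci[:, 0] <= ci[:, 1])


class TestCredibleInterval:
    def _chain(self, draws):
        return MCMCChain(np.asarray(draws), burn_in=0, accept_rates=np.full(4, 0.3))

    def test_constant_chain(self):
        chain = self._chain(np.tile([1.0, 2.0, 3.0, 4.0], (500, 1)))
        ci = credible_interval(chain, 0.95)
        np.testing.assert_allclose(ci[:, 0], [1, 2, 3, 4])
        np.testing.assert_allclose(ci[:, 1], [1, 2, 3, 4])

    def test_normal_quantiles(self):
        rng = np.random.default_rng(3)
        chain = self._chain(rng.standard_normal((50_000, 4)))
        ci = credible_interval(chain, 0.95)
        np.testing.assert_allclose(ci[:, 0], -1.96, atol=0.05)
        np.testing.assert_allclose(ci[:, 1], 1.96, atol=0.05)

    def test_widens_with_level(self):
        rng = np.random.default_rng(4)
        chain = self._chain(rng.standard_normal((5_000, 4)))
        w80 = np.diff(credible_interval(chain, 0.80)).ravel()
        w95 = np.diff(credible_interval(chain, 0.95)).ravel()
        assert np.all(w95 > w80)

    def test_short_chain_rejected(self):
        chain = self._chain(np.ones((50, 4)))
        with pytest.raises(ValueError):
            credible_interval(chain, 0.95)
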
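# biwrss

Estimation of the Marshall–Olkin **bivariate inverse Weibull** (BIW)
distribution under **ranked-set sampling** (RSS) with a concomitant
variable, compared against simple random sampling (SRS).

## Who this is for

Reliability engineers, survival analysts and sampling statisticians working
with paired heavy-tailed measurements (component lifetimes, anthropometric
pairs, environmental extremes) where one variable is cheap to *rank* but the
pair is expensive to *measure*. Ranked-set sampling measures only the i-th
ranked unit of the i-th size-m set per cycle, and typically buys a large
efficiency gain over SRS at the same number of measured units.

## The model

Three independent latent lifetimes U_k ~ IW(α, λ_k), with common shape α and
inverse-Weibull cdf F(u) = exp(−λ u^−α), are combined by the Marshall–Olkin
maximum construction

    X = max(U₁, U₃),   Y = max(U₂, U₃).

Then (X, Y) ~ BIW(α, λ₁, λ₂, λ₃): the marginals are IW(α, λ₁+λ₃) and
IW(α, λ₂+λ₃), max(X, Y) ~ IW(α, λ₁+λ₂+λ₃), and the common shock U₃ induces
both dependence and a singular component on the diagonal with
P(X = Y) = λ₃/(λ₁+λ₂+λ₃). The joint density has three branches (x<y, x>y,
x=y), recorded per observation by event indicators (δ₁, δ₂, δ₃).

For an RSS of set size m and r cycles the likelihood of the kept pair
(x₍ᵢ₎ⱼ, y₍ᵢ₎ⱼ) picks up the order-statistic factors
F_X(x)^(i−1) [1 − F_X(x)]^(m−i) with F_X the marginal cdf of the ranking
variable; SRS is the degenerate case m = 1.

Two estimation routes are provided:

* **Maximum likelihood** — Newton–Raphson on log parameters with
  step-halving (accepted steps never decrease the likelihood), convergence
  when the largest update falls below 1e−6, and Wald intervals
  θ̂ ± z_{γ/2}·√v_kk from the inverse observed information.
* **Bayesian** — independent Gamma(a_i, b_i) priors on (λ₁, λ₂, λ₃) are
  conjugate after binomial expansion of the mixed-rate powers: with known α
  the posterior is an exact (signed, for RSS) mixture of products of gamma
  densities and the squared-error-loss estimator is its mean in closed form.
  With α unknown a seeded Metropolis-within-Gibbs sampler targets
  prior × likelihood on log parameters.

A vectorised Monte-Carlo engine reproduces design-comparison studies: MSE,
bias, relative efficiency EFF = MSE_SRS/MSE_RSS, empirical interval
coverage, and prior-sensitivity tables.

## Worked example

```python
import numpy as np
from biwrss import BIWParams, draw_rss, BIWMaximumLikelihood, BIWBayes

truth = BIWParams(alpha=1.0, lam1=0.5, lam2=1.0, lam3=1.0)
sample = draw_rss(truth, m=5, r=6, seed=1)      # 30 measured pairs
print(sample.n1, sample.n2, sample.n3)          # 11 5 14

mle = BIWMaximumLikelihood().fit(sample)
print(np.round([mle.alpha_, mle.lam1_, mle.lam2_, mle.lam3_], 4))
# [1.0793 0.432  0.7698 0.9792]
print(np.round(mle.conf_int_[0], 4))            # 95% Wald CI for alpha
# [0.8787 1.2798]

bay = BIWBayes(random_state=1).fit(sample)      # gamma priors, MCMC
print(np.round([bay.alpha_, bay.lam1_, bay.lam2_, bay.lam3_], 4))
# [1.0916 0.5003 0.8361 0.9625]
```

The 30-observation ranked-set sample contains 11 pairs with x < y, 5 with
x > y and 14 exact ties (the common-shock diagonal; the expected tie
fraction here is λ₃/λ₁₂₃ = 0.4). Both routes recover the generating
parameters well within their intervals; the Bayes point estimates are
shrunk toward the prior means.

The same is available from the shell:

```sh
biwrss simulate --design rss --m 5 --r 6 --alpha 1 --lam 0.5 --lam 1 --lam 1 \
    --seed 1 --out rss.csv
biwrss fit mle --data rss.csv --out fit.json
biwrss study --out study/ --reps 1000 --seed 1      # MSE/Bias/EFF grid
```

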
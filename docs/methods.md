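# Methods

## Model

BIW(α, λ₁, λ₂, λ₃) is the Marshall–Olkin maximum construction over three
independent inverse Weibull lifetimes with a common shape α: X = max(U₁, U₃),
Y = max(U₂, U₃), U_k ~ IW(α, λ_k), F_IW(u) = exp(−λ u^−α). Closure of the IW
family under maxima (rates add at fixed shape) gives marginals
X ~ IW(α, λ₁₃), Y ~ IW(α, λ₂₃) and max(X, Y) ~ IW(α, λ₁₂₃), writing
λ₁₃ = λ₁+λ₃ etc. On the latent exponential scale T_k = U_k^−α ~ Exp(λ_k) the
construction is the classical common-shock model; ties {X = Y} occur exactly
when the shock dominates, so the distribution has a singular diagonal
component of mass P(X = Y) = λ₃/λ₁₂₃ and the joint density has two
absolutely continuous branches plus a one-dimensional diagonal density
λ₃ α x^{−α−1} e^{−λ₁₂₃ x^{−α}}.

Conventions. Parameter order is (α, λ₁, λ₂, λ₃) everywhere. All densities
are evaluated in log space (x^{−α−1} overflows while the exponential factor
underflows; their product is benign). λ₃ = 0 is accepted as the documented
independence limit and simply zeroes the diagonal mass; other non-positive
parameters are rejected. In the x > y branch the exponent pairs λ₁ with x
and λ₂₃ with y — the form obtained by differentiating the piecewise joint
cdf, which is also the form the SRS log-likelihood uses.

## Sampling designs

SRS is drawn by inverse transform, Z_k = (−λ_k / ln U_k)^{1/α}, X = max(Z₁,
Z₃), Y = max(Z₂, Z₃); ties are *exact* floating-point equalities (both
coordinates equal Z₃), so event indicators use literal equality. An RSS
cycle draws m² pairs, partitions them into m sets of m, ranks each set by
the X coordinate (ascending, ties broken by draw order — a probability-zero
event for this continuous model), and keeps the i-th order statistic of set
i with its concomitant Y; r cycles give n = m·r measured pairs. Concomitants
always travel with their X; nothing is re-sorted downstream.

Ranking is on X because the ranked-term factors of the likelihood involve
the marginal cdf of X evaluated at the kept x values; the design and the
likelihood must agree on which variable is ranked.

## Likelihood, score, information

Both designs share one kernel. Each observation carries (δ₁, δ₂, δ₃) and
rank weights w₁ = i−1, w₂ = m−i (zero for SRS):

l = (2N₁+2N₂+N₃) log α + N₁(log λ₁₃ + log λ₂) + N₂(log λ₂₃ + log λ₁)
  + N₃ log λ₃ − (α+1)[Σ log x + Σ_{δ₁+δ₂} log y]
  − λ₂Z₁ − λ₁Z₂ − λ₂₃Z₃ − λ₁₃Z₄ − λ₁₂₃Z₅ + Σ w₂ log(1 − e^{−λ₁₃ x^{−α}}),

with Z₁ = Σδ₁y^{−α}, Z₂ = Σδ₂x^{−α}, Z₃ = Σδ₂y^{−α}, Z₄ = Σ(δ₁+w₁)x^{−α},
Z₅ = Σδ₃x^{−α}. The log α coefficient counts two powers of α for each
off-diagonal observation and one for each tie. Gradient and Hessian are
exact analytic derivatives of this expression; the test suite checks both
against central finite differences on randomized instances, and checks the
log-likelihood itself against an independent branch-sum oracle built from
the joint density and marginal cdf. The λ₁–λ₂ cross-derivative vanishes
identically under SRS.

Newton–Raphson runs on log parameters (positivity without constraints),
with the Newton direction replaced by the gradient when it is not an ascent
direction, a log-scale step cap of 4, and up to 30 step-halvings whenever
the objective would decrease — accepted steps never lower the
log-likelihood. Convergence: largest update below 1e−6 (or 200 iterations).
Fits whose parameters leave [1e−5, 1e5] are flagged non-converged (the
likelihood is drifting to a boundary, e.g. λ̂₃ → 0 when no ties occurred).
The variance matrix is the inverse *observed* information at the optimum
(the expected information has no closed form here); a pseudo-inverse is
used, and flagged, if the Hessian is singular. Wald intervals are
θ̂ ± z_{γ/2}√v_kk.

Default initialisation: α from the log-scale spread of W = max(x, y)
(sd(log W) = π/(α√6) for W ~ IW), λ₁₂₃ from the log-scale mean, and the
split of λ₁₂₃ from the event frequencies P(x>y) = λ₁/λ₁₂₃,
P(x<y) = λ₂/λ₁₂₃, P(x=y) = λ₃/λ₁₂₃ with half-count smoothing. Degenerate
samples (N₁ = 0 or N₂ = 0) still fit but warn: the corresponding 1/λ score
terms vanish and identifiability weakens.

## Bayesian estimation

Independent Gamma(a_i, b_i) priors on (λ₁, λ₂, λ₃); presets: baseline
(shapes 2, rate 1), noninformative (shapes 1, rate 0.5), alternative
(shape 2, rate 1 — numerically identical to baseline; kept as a named
preset so sensitivity protocols can reference it). Three separate rates are
carried even though the presets share one value.

With α known, expanding (λ₁+λ₃)^{N₁} and (λ₂+λ₃)^{N₂} binomially — sums
from 0, which is required for the mixture to integrate to the posterior —
and, for RSS, each ranked factor (1 − e^{−λ₁₃x^{−α}})^{m−i} into signed
exponentials (one expansion index per observation, distributed into a full
cross-product), the posterior is an exact finite mixture of products of
three gamma densities. Component count (N₁+1)(N₂+1)·Π(m−i+1) is
capacity-guarded at 10⁶; beyond that the code directs to MCMC. Signed
weights are normalised in log space with sign bookkeeping. The λ₃ shape of
component (k, s) is a₃ + N − k − s with N the total count. The SELF
estimator is the mixture mean Σ w_c · shape_c/rate_c. Correctness is
pinned by a three-way triangle on small fixtures: closed form = 3-D
log-grid quadrature = MCMC, plus an importance-sampling cross-check and a
unit-integral check of the mixture density.

With α unknown, Metropolis-within-Gibbs with Gaussian random walks on each
log parameter targets prior × likelihood (including the log-transform
Jacobian); α gets a Gamma(2, 1) prior by default. Proposal scales adapt
toward 30% acceptance during burn-in only (detailed balance holds after
freezing). Defaults for standalone fits: 10,000 iterations, 2,000 burn-in;
point estimates are post-burn-in means, credible intervals the 2.5/97.5
percentiles. Chains are reproducible bit-for-bit under a fixed seed;
acceptance rates outside [0.1, 0.6] raise a warning flag.

## Monte-Carlo study engine

A cell = (design, estimator, set size m) at a fixed truth. Protocol:

* r = 1 cycle, so the cell sample size is n = m and the SRS comparison uses
  the same n; EFF = MSE_SRS/MSE_RSS is then a fixed-measurement-cost
  comparison. r is exposed as a knob.
* Newton and MCMC start at the true parameters (the usual simulation-study
  protocol; standalone fits use the data-driven initialiser).
* Non-converged MLE replications are redrawn from the same stream and
  counted; a cell with more than 5% redraws is flagged. At n = 5 the redraw
  fraction is substantial (an empty event category sends a rate to its
  boundary), so reported cells are implicitly conditional on convergence.
* Study-cell MCMC uses 3,000 iterations with 1,000 burn-in — shorter than
  the standalone default; with 1,000 replications the extra posterior-mean
  noise is well below the Monte-Carlo error of the cell summary.
* Per-cell RNG streams are derived from (master seed, truth, design,
  estimator, m, r), so results are independent of execution order;
  replications are vectorised (batched Newton and batched chains), not
  farmed to worker processes.

Cell summaries report MSE, bias and their Monte-Carlo standard errors;
coverage cells report the fraction of replications whose Wald (MLE) or
2.5–97.5 percentile (Bayes) interval contains the truth. The prior
sensitivity table runs the Bayes λ estimators with α treated as known, at
truth (α=1.5; λ = 0.2, 0.8, 0.4), m = 10, for the three named presets.

## What the generator does and does not emulate

The synthetic data are exact draws from the BIW model with perfect ranking
and exact common-shock ties. Real paired data never tie exactly (the CSV
reader therefore treats only exact equality as a tie by default, with an
explicit `tie_tol` opt-in), rankings may be imperfect, and marginals need
not be inverse Weibull — none of which the passing tests speak to.

## Known limitations and caveats

* Small-sample MLE summaries are heavy-tailed: λ̂ scales like c^α̂ under a
  scale change, so at n = 5 a handful of converged replications with large
  α̂ produce enormous λ̂ and the empirical MSE of λ̂ is unstable across
  seeds (its population counterpart may not be finite). MSE comparisons at
  such sizes are only meaningful under an explicit truncation rule, which
  this package deliberately does not impose.
* Bayes cell summaries depend materially on the prior when n is small; with
  the baseline priors (mean 2) and rates well below 2, prior-induced bias is
  design-independent and can erase the RSS efficiency advantage in
  individual cells.
* Wald intervals rely on asymptotic normality; their measured coverage at
  m = 15 is near nominal, but smaller designs undercover.
* Expected (rather than observed) Fisher information, profile or bootstrap
  intervals, censoring, imperfect ranking and unbalanced RSS variants are
  out of scope.
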
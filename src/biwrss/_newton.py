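"""Batched Newton-Raphson maximiser for the BIW log-likelihood.

The iteration runs on log parameters phi = log(alpha, lam1, lam2, lam3),
which enforces positivity without a constrained solver.  Each step solves
the Newton system on the log scale, falls back to the gradient direction
when the Newton direction is not an ascent direction, and applies
step-halving (up to ``max_halvings`` times) whenever the log-likelihood
would decrease, so accepted steps never lower the objective.  Convergence
is declared when the largest parameter update falls below ``tol``.

Everything is vectorised over a leading replication axis so that the
Monte-Carlo study can run thousands of fits as one array program.
"""

from __future__ import annotations

import numpy as np

from .likelihood import LikelihoodData, _loglik, _score_hessian

# fits whose parameters escape [1/PARAM_BOUND, PARAM_BOUND] are flagged as
# non-converged (the likelihood is drifting to a boundary, e.g. lam3 -> 0
# when no ties were observed)
PARAM_BOUND = 1e5
_LOG_BOUND = np.log(PARAM_BOUND)
_EULER_GAMMA = 0.5772156649015329


def moment_init(data: LikelihoodData) -> np.ndarray:
    """Data-driven starting values, batched.

    alpha from the log-scale spread of W = max(x, y) ~ IW(alpha, lam123)
    (log W has standard deviation pi / (alpha sqrt 6)); lam123 from the log
    mean; the split between lam1, lam2, lam3 from the event frequencies
    P(x>y) = lam1/lam123, P(x<y) = lam2/lam123, P(x=y) = lam3/lam123, with
    half-count smoothing so empty categories stay off the boundary.
    """
    lw = np.maximum(data.lx, data.ly)
    sd = lw.std(axis=-1)
    alpha = np.pi / (np.sqrt(6.0) * np.where(sd > 0, sd, 1.0))
    alpha = np.clip(np.where(sd > 0, alpha, 1.0), 0.05, 50.0)
    lam123 = np.exp(np.clip(alpha * lw.mean(axis=-1) - _EULER_GAMMA, -15.0, 15.0))
    n = data.lx.shape[-1]
    p1 = (data.n1 + 0.5) / (n + 1.5)
    p2 = (data.n2 + 0.5) / (n + 1.5)
    p3 = (data.n3 + 0.5) / (n + 1.5)
    theta = np.stack([alpha, lam123 * p2, lam123 * p1, lam123 * p3], axis=-1)
    return theta


def _solve_direction(neg_hess, grad):
    """Ascent direction: Newton when usable, gradient otherwise."""
    neg = np.where(np.isfinite(neg_hess), neg_hess, 0.0)
    bad = ~np.isfinite(neg_hess).all(axis=(-2, -1))
    if np.any(bad):
        neg[bad] = np.eye(4)
    try:
        d = np.linalg.solve(neg, grad[..., None])[..., 0]
    except np.linalg.LinAlgError:
        d = np.einsum("...ij,...j->...i", np.linalg.pinv(neg), grad)
    ascent = np.einsum("...i,...i->...", grad, d)
    use_grad = (~np.isfinite(d).all(axis=-1)) | (ascent <= 0.0)
    d = np.where(use_grad[..., None], grad, d)
    # cap the log-scale step length; step-halving handles the rest
    mx = np.max(np.abs(d), axis=-1, keepdims=True)
    d = d * np.minimum(1.0, 4.0 / np.maximum(mx, 1e-300))
    return d


def newton_mle_batch(
    theta0: np.ndarray,
    data: LikelihoodData,
    tol: float = 1e-6,
    max_iter: int = 200,
    max_halvings: int = 30,
):
    """Maximise the log-likelihood from ``theta0`` (batched, shape (..., 4)).

    Returns a dict with ``theta`` (natural scale), ``loglik``, ``converged``,
    ``n_iter``, ``grad_norm``, ``vcov`` (inverse observed information on the
    natural scale) and ``singular`` (pseudo-inverse fallback flag).
    """
    theta0 = np.asarray(theta0, dtype=float)
    batch = theta0.shape[:-1]
    phi = np.log(theta0)
    ll = _loglik(np.exp(phi), data)
    active = np.ones(batch, dtype=bool)
    converged = np.zeros(batch, dtype=bool)
    n_iter = np.zeros(batch, dtype=int)
    diag = np.arange(4)

    for _ in range(max_iter):
        if not active.any():
            break
        theta = np.exp(phi)
        grad, hess = _score_hessian(theta, data)
        gphi = grad * theta
        hphi = hess * theta[..., :, None] * theta[..., None, :]
        hphi[..., diag, diag] += gphi
        d = _solve_direction(-hphi, gphi)

        # vectorised step-halving: shrink until the log-likelihood ascends
        step = np.ones(batch)
        accepted = np.zeros(batch, dtype=bool)
        new_phi = phi.copy()
        new_ll = ll.copy()
        for _h in range(max_halvings + 1):
            todo = active & ~accepted
            if not todo.any():
                break
            trial = phi + np.where(todo, step, 0.0)[..., None] * d
            trial = np.clip(trial, -_LOG_BOUND - 1.0, _LOG_BOUND + 1.0)
            llt = _loglik(np.exp(trial), data)
            ok = todo & np.isfinite(llt) & (llt >= ll - 1e-10)
            new_phi = np.where(ok[..., None], trial, new_phi)
            new_ll = np.where(ok, llt, new_ll)
            accepted |= ok
            step = np.where(accepted, step, step * 0.5)

        dphi = np.max(np.abs(new_phi - phi), axis=-1)
        phi, ll = new_phi, new_ll
        n_iter += active
        done = accepted & (dphi < tol)
        # rows that found no ascending step are stuck; stop them (they count
        # as converged only if already at a stationary point)
        stuck = active & ~accepted
        done |= stuck & (np.max(np.abs(gphi), axis=-1) < 1e-4)
        converged |= done & active
        active &= ~done & ~stuck

    theta = np.exp(phi)
    out_of_bounds = np.max(np.abs(phi), axis=-1) > _LOG_BOUND
    converged &= ~out_of_bounds & np.isfinite(ll)

    grad, hess = _score_hessian(theta, data)
    neg = np.where(np.isfinite(hess), -hess, 0.0)
    vcov = np.empty(batch + (4, 4))
    try:
        vcov[...] = np.linalg.inv(neg)
        singular = np.zeros(batch, dtype=bool)
    except np.linalg.LinAlgError:
        vcov[...] = np.linalg.pinv(neg)
        singular = np.ones(batch, dtype=bool)
    bad = ~np.isfinite(vcov).all(axis=(-2, -1))
    if np.any(bad):
        vcov[bad] = np.nan
        singular |= bad
    return {
        "theta": theta,
        "loglik": ll,
        "converged": converged,
        "n_iter": n_iter,
        "grad_norm": np.max(np.abs(grad), axis=-1),
        "vcov": vcov,
        "singular": singular,
    }
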
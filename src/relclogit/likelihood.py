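"""Exploded-logit ranking likelihood and its marginalization.

A ranking of 3 alternatives is treated as two sequential conditional-logit
choices: the best of all three, then the better of the two remaining, both
driven by the same deterministic utilities.  The marginal likelihood of a
participant mixes over latent classes (multinomial-logit prior on covariates)
and integrates the D standard-normal random effects on a quadrature grid.
All accumulation is done in log space with log-sum-exp stabilization; the
class × node cells are evaluated as one batched matrix product.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

from .data import RankingDataset
from .params import RELCLParams
from .quadrature import QuadratureGrid, gauss_hermite_grid

__all__ = [
    "ranking_logprob",
    "conditional_loglik",
    "marginal_loglik",
    "cond_loglik_matrix",
    "posterior_weights",
]


def build_exploded_cache(Z, first, second) -> dict:
    """Gather matrices reused across likelihood evaluations on one dataset:
    coded rows of the chosen alternatives, of the second-stage choice set
    (every alternative except the first choice), and their sums."""
    n, T, M, P = Z.shape
    ii = np.arange(n)[:, None]
    tt = np.arange(T)[None, :]
    Zf = np.ascontiguousarray(Z[ii, tt, first])  # (n, T, P)
    Zs = np.ascontiguousarray(Z[ii, tt, second])
    # remaining alternatives after the first choice, (n, T, M-1, P)
    others = np.argsort(np.arange(M) == first[:, :, None], kind="stable", axis=2)
    others = others[:, :, : M - 1]
    Zo = np.take_along_axis(Z, others[..., None], axis=2)
    return {
        "Z": Z, "first": first, "second": second,
        "Zf": Zf, "Zs": Zs, "Zo": np.ascontiguousarray(Zo),
        "A": (Zf + Zs).sum(axis=1),
    }


def _batch_forward(cache: dict, B) -> dict:
    """Forward pass of the batched exploded logit for coefficient rows
    B (K, P): per-participant log-likelihoods plus the intermediates the
    gradient needs.  The two-stage ranking probability for a task is softmax
    over all M alternatives at the first choice times softmax over the
    remaining M−1 at the second."""
    Z = cache["Z"]
    Bt = B.T
    U = Z @ Bt  # (n, T, M, K)
    Umax = U.max(axis=2)  # (n, T, K)
    uf = cache["Zf"] @ Bt
    us = cache["Zs"] @ Bt
    e1 = np.exp(U - Umax[:, :, None, :])
    Z1 = e1.sum(axis=2)  # (n, T, K)
    # second stage: direct sum over the remaining alternatives (numerically
    # stable even when the first choice dominates)
    eo = np.exp(cache["Zo"] @ Bt - Umax[:, :, None, :])  # (n, T, M-1, K)
    Z2 = eo.sum(axis=2)
    ll = (uf + us - 2.0 * Umax - np.log(Z1) - np.log(Z2)).sum(axis=1)
    return {"ll": ll, "e1": e1, "Z1": Z1, "eo": eo, "Z2": Z2}


def _batch_grad(cache: dict, state: dict, weights=None) -> np.ndarray:
    """Weighted gradient G (K, P), G[k] = Σ_i w[i,k] ∂ll_ik/∂b_k, from a
    forward-pass state.  ∂ll/∂b = z_first + z_second − Σ_m (p1 + p2)_m z_m
    with p2 zero at the first choice; assembled from three matrix products."""
    Z = cache["Z"]
    n, T, M, P = Z.shape
    e1, Z1, eo, Z2 = state["e1"], state["Z1"], state["eo"], state["Z2"]
    K = e1.shape[-1]
    w = np.ones((n, K)) if weights is None else weights
    G = w.T @ cache["A"]
    p1 = e1 / Z1[:, :, None, :]
    p1 *= w[:, None, None, :]
    G -= p1.reshape(n * T * M, K).T @ Z.reshape(n * T * M, P)
    p2 = eo / Z2[:, :, None, :]
    p2 *= w[:, None, None, :]
    G -= p2.reshape(n * T * (M - 1), K).T @ cache["Zo"].reshape(n * T * (M - 1), P)
    return G


def _exploded_batch(cache: dict, B, weights=None, need_grad=False):
    """Batched exploded-logit log-likelihood; see :func:`_batch_forward`."""
    state = _batch_forward(cache, B)
    if not need_grad:
        return state["ll"], None
    return state["ll"], _batch_grad(cache, state, weights)


def exploded_loglik(Z, first, second, b, weights=None, need_grad=False,
                    cache: dict | None = None):
    """Per-participant exploded log-likelihood under one coefficient vector.

    Returns ll (n,); with ``need_grad`` also the weighted gradient
    Σ_i w_i ∂ll_i/∂b of shape (P,).
    """
    b = np.asarray(b, dtype=float)
    if cache is None:
        cache = build_exploded_cache(Z, first, second)
    w = None if weights is None else np.asarray(weights)[:, None]
    ll, G = _exploded_batch(cache, b[None, :], w, need_grad)
    if not need_grad:
        return ll[:, 0]
    return ll[:, 0], G[0]


def ranking_logprob(utilities: np.ndarray, first: int, second: int) -> float:
    """Log probability of choosing ``first`` best and ``second`` second-best
    (0-based indices) under the exploded logit with the given utilities."""
    u = np.asarray(utilities, dtype=float)
    if u.ndim != 1 or len(u) < 2:
        raise ValueError("utilities must be a vector of >= 2 values")
    if not np.all(np.isfinite(u)):
        raise ValueError("utilities must be finite")
    M = len(u)
    if not (0 <= first < M and 0 <= second < M) or first == second:
        raise ValueError("first/second must be distinct valid indices")
    Z = np.eye(M)[None, None, :, :]  # utilities as their own 'coefficients'
    ll = exploded_loglik(Z, np.array([[first]]), np.array([[second]]), u)
    return float(ll[0])


def conditional_loglik(
    params: RELCLParams,
    dataset: RankingDataset,
    x: int,
    F: np.ndarray,
    participant: int | None = None,
) -> float | np.ndarray:
    """Log-likelihood of the observed rankings given class x (0-based) and
    random-effect scores F (length D); all participants, or one."""
    F = np.asarray(F, dtype=float).reshape(-1)
    if F.shape[0] != params.n_effects:
        raise ValueError(f"F must have {params.n_effects} entries")
    if not 0 <= x < params.n_classes:
        raise ValueError("class index out of range")
    b = params.beta[x] + params.lam.T @ F
    ll, _ = _exploded_batch(dataset.exploded_cache(), b[None, :])
    return ll[:, 0] if participant is None else float(ll[participant, 0])


def _cell_coefs(params: RELCLParams, grid: QuadratureGrid) -> np.ndarray:
    """(X·Q, P) coefficient vectors β_x + λᵀ f_q, cells ordered x-major."""
    coefs = params.beta[:, None, :] + grid.nodes @ params.lam  # (X, Q, P)
    return coefs.reshape(-1, params.n_contrasts)


def cond_loglik_matrix(
    params: RELCLParams, dataset: RankingDataset, grid: QuadratureGrid
) -> np.ndarray:
    """(n, X, Q) conditional log-likelihoods at every class × node."""
    if grid.n_dim != params.n_effects:
        raise ValueError("grid dimension must equal the number of random effects")
    ll, _ = _exploded_batch(dataset.exploded_cache(), _cell_coefs(params, grid))
    return ll.reshape(dataset.n_participants, params.n_classes, grid.n_nodes)


def _log_joint(params, dataset, grid, cond=None):
    if cond is None:
        cond = cond_loglik_matrix(params, dataset, grid)
    log_pi = params.membership_logits(dataset.membership_design())  # (n, X)
    return cond + log_pi[:, :, None] + np.log(grid.weights)[None, None, :]


def marginal_loglik(
    params: RELCLParams,
    dataset: RankingDataset,
    grid: QuadratureGrid | None = None,
    n_nodes: int = 7,
) -> float:
    """Total log-likelihood, mixing over classes and integrating the random
    effects: Σ_i log Σ_x π_x(i) Σ_q w_q exp ℓ_i(x, f_q)."""
    if grid is None:
        grid = gauss_hermite_grid(params.n_effects, n_nodes)
    lj = _log_joint(params, dataset, grid)
    per = logsumexp(lj.reshape(len(lj), -1), axis=1)
    if not np.all(np.isfinite(per)):
        raise FloatingPointError("non-finite likelihood: degenerate parameters")
    return float(per.sum())


def posterior_weights(params, dataset, grid, cond=None):
    """Joint posterior over (class, node) per participant.

    Returns (w, loglik): w is (n, X, Q), rows summing to 1.
    """
    lj = _log_joint(params, dataset, grid, cond)
    flat = lj.reshape(len(lj), -1)
    per = logsumexp(flat, axis=1)
    w = np.exp(lj - per[:, None, None])
    return w, float(per.sum())


def weighted_utility_grads(params, dataset, grid, w):
    """Posterior-weighted value and gradients of the exploded term:
    returns (Σ w∘ll, ∂/∂β (X, P), ∂/∂λ (D, P))."""
    n = dataset.n_participants
    X, Q = params.n_classes, grid.n_nodes
    ll, G = _exploded_batch(
        dataset.exploded_cache(), _cell_coefs(params, grid),
        weights=w.reshape(n, X * Q), need_grad=True,
    )
    val = float((w.reshape(n, X * Q) * ll).sum())
    Gc = G.reshape(X, Q, -1)
    gbeta = Gc.sum(axis=1)
    glam = np.einsum("qd,xqp->dp", grid.nodes, Gc) if params.n_effects else \
        np.zeros((0, params.n_contrasts))
    return val, gbeta, glam


def _gamma_grad(params, dataset, w):
    """Gradient of the marginal log-likelihood w.r.t. the membership logit
    coefficients (reference class = last)."""
    if params.n_classes == 1:
        return np.zeros((0, 0))
    W = dataset.membership_design()
    pi = np.exp(params.membership_logits(W))  # (n, X)
    wbar = w.sum(axis=2)  # (n, X)
    resid = wbar - pi
    return resid[:, :-1].T @ W  # (X-1, 1+C)


def marginal_negloglik_and_grad(theta, template: RELCLParams, dataset, grid):
    """Negative marginal log-likelihood and exact gradient (Fisher's
    identity: the score equals the posterior-weighted complete-data score)
    for quasi-Newton refinement on the packed parameter vector."""
    params = template.unpack(np.asarray(theta, dtype=float))
    cache = dataset.exploded_cache()
    n, X, Q = dataset.n_participants, params.n_classes, grid.n_nodes
    state = _batch_forward(cache, _cell_coefs(params, grid))
    cond = state["ll"].reshape(n, X, Q)
    w, ll = posterior_weights(params, dataset, grid, cond)
    G = _batch_grad(cache, state, w.reshape(n, X * Q)).reshape(X, Q, -1)
    gbeta = G.sum(axis=1)
    glam = np.einsum("qd,xqp->dp", grid.nodes, G) if params.n_effects else \
        np.zeros((0, params.n_contrasts))
    ggamma = _gamma_grad(params, dataset, w)
    grad = np.concatenate(
        [gbeta.ravel(), glam[params.domain_mask], ggamma.ravel()]
    )
    return -ll, -grad
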
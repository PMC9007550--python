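"""Maximum-likelihood estimation of the random effects latent class logit.

The fitting schedule mirrors standard mixture-model practice for these
models: an EM phase (joint posteriors over class × quadrature node in the
E-step; weighted exploded-logit and weighted multinomial-logit maximizations
in the M-step) until the log-likelihood change falls below tolerance, then a
quasi-Newton (L-BFGS-B) refinement of the full marginal likelihood using the
exact gradient from Fisher's identity.  Multiple random starts guard against
local optima; the best start is reported after canonicalization (classes
ordered by descending size, loading signs fixed per domain).
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .data import RankingDataset
from .likelihood import (
    cond_loglik_matrix,
    marginal_negloglik_and_grad,
    posterior_weights,
    weighted_utility_grads,
)
from .params import RELCLParams, n_free_params
from .quadrature import QuadratureGrid, gauss_hermite_grid, halton_grid
from .scheme import AttributeScheme, expand_contrasts

__all__ = ["FitConfig", "FitResult", "init_params", "em_step", "fit", "fit_grid",
           "canonicalize", "align_parameters"]


@dataclass(frozen=True)
class FitConfig:
    """Estimation settings.

    ``n_starts`` random initializations each get up to ``em_iterations`` EM
    steps (stopping early when the log-likelihood improves by less than
    ``tol``) followed by up to ``newton_iterations`` quasi-Newton iterations
    on the full marginal likelihood.  ``refit_starts`` is the wider
    multi-start used to confirm a selected model.  ``bic_sample_size``
    chooses the BIC N: participants (mixture convention for repeated
    measures) or exploded choices.
    """

    em_iterations: int = 250
    newton_iterations: int = 50
    n_starts: int = 16
    refit_starts: int = 150
    tol: float = 1e-4
    seed: int = 0
    n_nodes: int = 7
    integration: str = "gauss-hermite"  # or "halton"
    n_draws: int = 200
    mstep_maxiter: int = 25
    beta_start_sd: float = 0.5
    order_constraint: bool = True
    bic_sample_size: str = "participants"  # or "choices"
    standard_errors: bool = False

    def __post_init__(self) -> None:
        if min(self.em_iterations, self.newton_iterations, self.n_starts) < 1:
            raise ValueError("iteration and start counts must be positive")
        if self.tol <= 0:
            raise ValueError("tolerance must be positive")

    def make_grid(self, n_effects: int) -> QuadratureGrid:
        if self.integration == "halton":
            return halton_grid(n_effects, self.n_draws, seed=self.seed)
        return gauss_hermite_grid(n_effects, self.n_nodes)


@dataclass
class FitResult:
    """A fitted model: canonicalized parameters, fit statistics, and
    per-start diagnostics."""

    params: RELCLParams
    loglik: float
    n_params: int
    bic: float
    converged: bool
    best_start: int
    start_logliks: list[float]
    n_participants: int
    config: FitConfig
    em_iterations_used: int = 0
    se_beta_expanded: np.ndarray | None = None
    se_lam_expanded: np.ndarray | None = None
    se_gamma: np.ndarray | None = None

    @property
    def n_classes(self) -> int:
        return self.params.n_classes

    @property
    def n_effects(self) -> int:
        return self.params.n_effects

    def to_dict(self) -> dict:
        d = {
            "loglik": self.loglik,
            "n_params": self.n_params,
            "bic": self.bic,
            "converged": self.converged,
            "best_start": self.best_start,
            "start_logliks": self.start_logliks,
            "n_participants": self.n_participants,
            "em_iterations_used": self.em_iterations_used,
            "params": self.params.to_dict(),
        }
        if self.se_beta_expanded is not None:
            d["se_beta_expanded"] = self.se_beta_expanded.tolist()
            d["se_lam_expanded"] = self.se_lam_expanded.tolist()
            d["se_gamma"] = self.se_gamma.tolist()
        return d


def init_params(
    scheme: AttributeScheme,
    n_classes: int,
    n_effects: int,
    rng: np.random.Generator,
    beta_sd: float = 0.5,
    n_covariates: int = 1,
) -> RELCLParams:
    """Random starting values: β ~ N(0, beta_sd²), small positive loadings on
    the domain mask, γ = 0."""
    P = scheme.n_contrasts
    beta = rng.normal(0.0, beta_sd, size=(n_classes, P))
    mask = scheme.domain_mask(n_effects)
    lam = np.zeros((n_effects, P))
    lam[mask] = 0.05 + np.abs(rng.normal(0.0, 0.2, size=int(mask.sum())))
    gamma = np.zeros((n_classes - 1, 1 + n_covariates))
    return RELCLParams(scheme, beta, lam, gamma)


def _order_bounds(params: RELCLParams) -> list | None:
    """L-BFGS-B bounds enforcing the monotone-preference sign constraint on
    ordered two-level attributes: the free contrast (coefficient of the first,
    lower level) is constrained ≤ 0 so the higher level's expanded
    coefficient is ≥ 0.  Applies to β only."""
    scheme = params.scheme
    cols = [
        sl.start
        for a, sl in zip(scheme.attributes, scheme.contrast_slices())
        if a.ordered and a.n_levels == 2
    ]
    if not cols:
        return None
    X, P = params.beta.shape
    bounds = [(None, None)] * params.n_free
    for x in range(X):
        for c in cols:
            bounds[x * P + c] = (None, 0.0)
    return bounds


def _clip_to_bounds(theta: np.ndarray, bounds) -> np.ndarray:
    if bounds is None:
        return theta
    lo = np.array([-np.inf if b[0] is None else b[0] for b in bounds])
    hi = np.array([np.inf if b[1] is None else b[1] for b in bounds])
    return np.clip(theta, lo, hi)


# ---------------------------------------------------------------------------
# EM

def _mstep_utility(params, dataset, grid, w, maxiter, bounds):
    """Maximize the expected complete-data exploded-logit term over (β, λ)
    with posterior weights w fixed; returns updated params."""
    X, P, D = params.n_classes, params.n_contrasts, params.n_effects
    mask = params.domain_mask
    nb, nl = X * P, int(mask.sum())
    work = params.copy()

    def negQ(theta):
        work.beta = theta[:nb].reshape(X, P)
        work.lam = np.zeros((D, P))
        work.lam[mask] = theta[nb:]
        val, gbeta, glam = weighted_utility_grads(work, dataset, grid, w)
        grad = np.concatenate([gbeta.ravel(), glam[mask]])
        return -val, -grad

    theta0 = np.concatenate([params.beta.ravel(), params.lam[mask]])
    bl_bounds = None if bounds is None else bounds[: nb + nl]
    res = minimize(
        negQ, _clip_to_bounds(theta0, bl_bounds), jac=True, method="L-BFGS-B",
        bounds=bl_bounds, options={"maxiter": maxiter},
    )
    out = params.copy()
    out.beta = res.x[:nb].reshape(X, P)
    out.lam = np.zeros((D, P))
    out.lam[mask] = res.x[nb:]
    return out


def _mstep_membership(params, dataset, w, maxiter=100):
    """Weighted multinomial-logit M-step for γ (reference class last)."""
    if params.n_classes == 1:
        return params
    W = dataset.membership_design()
    wbar = w.sum(axis=2)  # (n, X)
    shape = params.gamma.shape

    def negQ(gvec):
        p = params.copy()
        p.gamma = gvec.reshape(shape)
        logpi = p.membership_logits(W)
        val = float((wbar * logpi).sum())
        resid = wbar - np.exp(logpi)
        grad = (resid[:, :-1].T @ W).ravel()
        return -val, -grad

    res = minimize(negQ, params.gamma.ravel(), jac=True, method="L-BFGS-B",
                   options={"maxiter": maxiter})
    out = params.copy()
    out.gamma = res.x.reshape(shape)
    return out


def em_step(
    params: RELCLParams,
    dataset: RankingDataset,
    grid: QuadratureGrid,
    mstep_maxiter: int = 25,
    bounds=None,
) -> tuple[RELCLParams, float]:
    """One EM step; returns updated params and the log-likelihood of the
    *input* params (from the E-step).  The marginal log-likelihood is
    non-decreasing across steps."""
    cond = cond_loglik_matrix(params, dataset, grid)
    w, ll = posterior_weights(params, dataset, grid, cond)
    if not np.isfinite(ll):
        raise FloatingPointError("posterior underflow: degenerate start")
    new = _mstep_utility(params, dataset, grid, w, mstep_maxiter, bounds)
    new = _mstep_membership(new, dataset, w)
    return new, ll


def _run_one_start(dataset, scheme, n_classes, n_effects, config, grid, rng):
    params = init_params(
        scheme, n_classes, n_effects, rng, beta_sd=config.beta_start_sd
    )
    bounds = _order_bounds(params) if config.order_constraint else None
    if bounds is not None:
        params = params.unpack(_clip_to_bounds(params.pack(), bounds))
    prev = -np.inf
    iters = 0
    for it in range(config.em_iterations):
        params, ll = em_step(params, dataset, grid, config.mstep_maxiter, bounds)
        iters = it + 1
        if ll - prev < config.tol and it > 0:
            break
        prev = ll
    # quasi-Newton refinement of the full marginal likelihood
    res = minimize(
        marginal_negloglik_and_grad,
        _clip_to_bounds(params.pack(), bounds),
        args=(params, dataset, grid),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": config.newton_iterations},
    )
    final = params.unpack(res.x)
    ll = -float(res.fun)
    converged = bool(res.success) or (ll - prev < 10 * config.tol)
    return final, ll, converged, iters


def canonicalize(params: RELCLParams, W: np.ndarray | None = None) -> RELCLParams:
    """Canonical labeling: classes sorted by descending average membership
    share (ties by first β coefficient), loading sign per domain fixed so the
    largest-magnitude expanded loading is positive.  Both transformations
    leave the marginal likelihood unchanged."""
    X = params.n_classes
    if W is None:
        W = np.array([[1.0, 0.0], [1.0, 1.0]])
    shares = params.class_shares(W)
    order = np.lexsort((params.beta[:, 0], -np.round(shares, 12)))
    gamma_full = np.vstack([params.gamma, np.zeros((1, params.gamma.shape[1]))]) \
        if X > 1 else np.zeros((1, 0))
    gamma_full = gamma_full[order]
    new_gamma = (gamma_full[:-1] - gamma_full[-1]) if X > 1 else np.zeros((0, 0))
    lam = params.lam.copy()
    if params.n_effects:
        lam_exp = expand_contrasts(params.scheme, lam)
        for d in range(params.n_effects):
            j = int(np.argmax(np.abs(lam_exp[d])))
            if lam_exp[d, j] < 0:
                lam[d] *= -1.0
    return RELCLParams(params.scheme, params.beta[order], lam, new_gamma)


def align_parameters(est: RELCLParams, ref: RELCLParams) -> RELCLParams:
    """Resolve the label-switching and loading-sign ambiguities of ``est``
    against a reference parameter set (e.g. a simulation truth): classes are
    permuted by minimum-cost matching of expanded β profiles, and each
    domain's loading sign is chosen to minimize the distance to the
    reference.  Both operations leave the likelihood unchanged."""
    from scipy.optimize import linear_sum_assignment

    if est.n_classes != ref.n_classes or est.n_effects != ref.n_effects:
        raise ValueError("parameter sets must share X and D")
    be, br = est.expanded_beta(), ref.expanded_beta()
    cost = np.abs(br[:, None, :] - be[None, :, :]).sum(axis=2)  # (ref, est)
    _, perm = linear_sum_assignment(cost)
    X = est.n_classes
    gamma_full = np.vstack([est.gamma, np.zeros((1, est.gamma.shape[1]))]) \
        if X > 1 else np.zeros((1, 0))
    gamma_full = gamma_full[perm]
    new_gamma = (gamma_full[:-1] - gamma_full[-1]) if X > 1 else np.zeros((0, 0))
    lam = est.lam.copy()
    for d in range(est.n_effects):
        if np.abs(-lam[d] - ref.lam[d]).sum() < np.abs(lam[d] - ref.lam[d]).sum():
            lam[d] *= -1.0
    return RELCLParams(est.scheme, est.beta[perm], lam, new_gamma)


def _standard_errors(result_params, dataset, grid):
    """Observed-information standard errors by numerical differentiation of
    the marginal score; expanded to per-level scale by the (linear)
    effects-coding expansion."""
    from statsmodels.tools.numdiff import approx_fprime

    theta = result_params.pack()

    def score(t):
        return marginal_negloglik_and_grad(t, result_params, dataset, grid)[1]

    H = approx_fprime(theta, score, centered=True)
    H = 0.5 * (H + H.T)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    scheme = result_params.scheme
    X, P, D = result_params.n_classes, result_params.n_contrasts, result_params.n_effects
    mask = result_params.domain_mask
    nb, nl = X * P, int(mask.sum())

    # linear expansion matrix free-contrasts -> per-level values
    A = expand_contrasts(scheme, np.eye(P)).T  # (n_levels_total, P)
    se_beta = np.empty((X, scheme.n_levels_total))
    for x in range(X):
        cb = cov[x * P : (x + 1) * P, x * P : (x + 1) * P]
        se_beta[x] = np.sqrt(np.clip(np.diag(A @ cb @ A.T), 0, None))
    se_lam = np.zeros((D, scheme.n_levels_total))
    if nl:
        cl_free = cov[nb : nb + nl, nb : nb + nl]
        E = np.zeros((nl, D * P))
        E[np.arange(nl), np.flatnonzero(mask.ravel())] = 1.0
        cov_lam = E.T @ cl_free @ E
        for d in range(D):
            cd = cov_lam[d * P : (d + 1) * P, d * P : (d + 1) * P]
            se_lam[d] = np.sqrt(np.clip(np.diag(A @ cd @ A.T), 0, None))
    se_gamma = np.sqrt(np.clip(np.diag(cov)[nb + nl :], 0, None)).reshape(
        result_params.gamma.shape
    )
    return se_beta, se_lam, se_gamma


def fit(
    dataset: RankingDataset,
    scheme: AttributeScheme | None = None,
    n_classes: int = 1,
    n_effects: int = 0,
    config: FitConfig | None = None,
) -> FitResult:
    """Fit an X-class, D-random-effect model by multi-start EM + quasi-Newton
    maximum likelihood and return the canonicalized best solution."""
    if dataset.n_participants < 1:
        raise ValueError("dataset is empty")
    scheme = scheme or dataset.scheme
    config = config or FitConfig()
    grid = config.make_grid(n_effects)
    rng = np.random.default_rng(config.seed)

    best = None
    logliks, any_converged = [], False
    for s in range(config.n_starts):
        try:
            params, ll, conv, iters = _run_one_start(
                dataset, scheme, n_classes, n_effects, config, grid, rng
            )
        except FloatingPointError:
            logliks.append(float("nan"))
            continue
        logliks.append(ll)
        any_converged |= conv
        if best is None or ll > best[1]:
            best = (params, ll, conv, s, iters)
    if best is None:
        raise RuntimeError("every start failed with a degenerate likelihood")
    params, ll, conv, s, iters = best
    params = canonicalize(params, dataset.membership_design())

    k = n_free_params(scheme, n_classes, n_effects, membership_covariates=1 if n_classes > 1 else 0)
    N = dataset.n_participants if config.bic_sample_size == "participants" \
        else dataset.n_choice_records
    result = FitResult(
        params=params,
        loglik=ll,
        n_params=k,
        bic=-2.0 * ll + k * np.log(N),
        converged=conv,
        best_start=s,
        start_logliks=logliks,
        n_participants=dataset.n_participants,
        config=config,
        em_iterations_used=iters,
    )
    if config.standard_errors:
        result.se_beta_expanded, result.se_lam_expanded, result.se_gamma = \
            _standard_errors(params, dataset, grid)
    return result


def fit_grid(
    dataset: RankingDataset,
    scheme: AttributeScheme | None = None,
    class_range=range(1, 11),
    re_range=range(0, 4),
    config: FitConfig | None = None,
) -> pd.DataFrame:
    """BIC model-selection grid over class counts × random-effect counts.

    Returns one row per (X, D) with loglik, n_params, BIC, convergence and an
    ``is_best`` flag on the BIC-minimizing row; failures in individual cells
    are recorded and the grid continues.
    """
    rows = []
    for X in class_range:
        for D in re_range:
            t0 = time.perf_counter()
            try:
                r = fit(dataset, scheme, X, D, config)
                rows.append(
                    dict(n_classes=X, n_effects=D, loglik=r.loglik,
                         n_params=r.n_params, bic=r.bic, converged=r.converged,
                         error="", seconds=time.perf_counter() - t0)
                )
            except Exception as exc:  # noqa: BLE001 - grid robustness
                rows.append(
                    dict(n_classes=X, n_effects=D, loglik=np.nan,
                         n_params=np.nan, bic=np.nan, converged=False,
                         error=str(exc), seconds=time.perf_counter() - t0)
                )
    df = pd.DataFrame(rows)
    df["is_best"] = False
    if df["bic"].notna().any():
        df.loc[df["bic"].idxmin(), "is_best"] = True
    return df
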
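"""Posterior (downstream) analyses of a fitted model.

Given a fitted random effects latent class logit, this module computes
per-participant posterior class probabilities and empirical-Bayes random
effect scores, individual-level preference values for density plots,
bias-adjusted three-step regressions of class membership and factor scores on
covariates, and the concordance of class assignments between two models.

The three-step correction follows the maximum-likelihood (modal assignment)
variant: the fitted measurement model gives each participant's posterior
class probabilities; modal assignments are treated as an error-prone
indicator of the true class with known misclassification rates, which are
absorbed into the step-3 multinomial logit instead of being ignored (the
naive regression, which attenuates covariate effects toward zero).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import linear_sum_assignment, minimize
from statsmodels.tools.numdiff import approx_hess

from .data import ANALYSIS_COVARIATES, RankingDataset
from .estimation import FitResult
from .likelihood import posterior_weights
from .params import RELCLParams

__all__ = [
    "PosteriorSummary",
    "ThreeStepResult",
    "class_posteriors",
    "individual_preferences",
    "three_step_membership",
    "regress_factor_scores",
    "concordance",
    "cohort_concordance",
]


@dataclass
class PosteriorSummary:
    """Per-participant posterior quantities and the classification table.

    ``probs`` (n, X) sums to 1 per row; ``modal`` is the argmax class
    (0-based, ties to the lower index); ``F_mean``/``F_sd`` (n, D) are
    posterior means and SDs of the random-effect scores;
    ``classification_matrix`` [j, k] is the average posterior probability of
    class k among participants modally assigned to class j (rows sum to 1).
    """

    probs: np.ndarray
    modal: np.ndarray
    F_mean: np.ndarray
    F_sd: np.ndarray
    classification_matrix: np.ndarray

    @property
    def n_classes(self) -> int:
        return self.probs.shape[1]

    def entropy(self) -> float:
        """Average classification entropy (0 = perfect separation)."""
        p = np.clip(self.probs, 1e-300, None)
        return float(-(p * np.log(p)).sum(axis=1).mean())

    def to_frame(self, participants: pd.DataFrame | None = None) -> pd.DataFrame:
        d = {}
        if participants is not None:
            d["participant"] = participants["participant"].to_numpy()
        for x in range(self.n_classes):
            d[f"p_class{x + 1}"] = self.probs[:, x]
        d["modal_class"] = self.modal + 1
        for j in range(self.F_mean.shape[1]):
            d[f"F{j + 1}_mean"] = self.F_mean[:, j]
            d[f"F{j + 1}_sd"] = self.F_sd[:, j]
        return pd.DataFrame(d)


def class_posteriors(fit: FitResult | RELCLParams, dataset: RankingDataset,
                     grid=None) -> PosteriorSummary:
    """Posterior class membership and empirical-Bayes factor scores.

    posterior_x(i) ∝ π_x(i) ∫ exp ℓ_i(x, F) dΦ(F); F scores are
    posterior-weighted node means (and SDs) over the joint (class × node)
    posterior.
    """
    if isinstance(fit, FitResult):
        params = fit.params
        grid = grid or fit.config.make_grid(params.n_effects)
    else:
        params = fit
        if grid is None:
            from .quadrature import gauss_hermite_grid

            grid = gauss_hermite_grid(params.n_effects, 7)
    w, _ = posterior_weights(params, dataset, grid)  # (n, X, Q)
    probs = w.sum(axis=2)
    modal = probs.argmax(axis=1)
    F_mean = w.sum(axis=1) @ grid.nodes  # (n, D)
    F2 = w.sum(axis=1) @ grid.nodes**2
    F_sd = np.sqrt(np.clip(F2 - F_mean**2, 0.0, None))
    X = params.n_classes
    cmat = np.empty((X, X))
    for j in range(X):
        sel = modal == j
        cmat[j] = probs[sel].mean(axis=0) if sel.any() else np.eye(X)[j]
    return PosteriorSummary(probs, modal, F_mean, F_sd, cmat)


def individual_preferences(
    params: RELCLParams | FitResult, posteriors: PosteriorSummary
) -> np.ndarray:
    """Individual-level expanded preference values (n, total levels):
    the modal class's per-level coefficients plus the loading-weighted
    posterior factor scores.  Per participant the values sum to zero within
    each attribute (linearity of the effects-coding expansion)."""
    if isinstance(params, FitResult):
        params = params.params
    be = params.expanded_beta()[posteriors.modal]  # (n, L)
    if params.n_effects:
        be = be + posteriors.F_mean @ params.expanded_lam()
    return be


def preferences_long(
    params: RELCLParams | FitResult,
    posteriors: PosteriorSummary,
    participants: pd.DataFrame,
) -> pd.DataFrame:
    """Long table (participant, class, attribute, level, value) for kernel-
    density plots of individual preference heterogeneity."""
    if isinstance(params, FitResult):
        params = params.params
    vals = individual_preferences(params, posteriors)
    labels = params.scheme.level_labels()
    n, L = vals.shape
    return pd.DataFrame(
        {
            "participant": np.repeat(participants["participant"].to_numpy(), L),
            "modal_class": np.repeat(posteriors.modal + 1, L),
            "attribute": np.tile([a for a, _ in labels], n),
            "level": np.tile([lv for _, lv in labels], n),
            "value": vals.reshape(-1),
        }
    )


# ---------------------------------------------------------------------------
# bias-adjusted three-step analysis


@dataclass
class ThreeStepResult:
    """Step-3 regression results.

    ``membership_coef`` / ``membership_se``: (X−1, 1+C) multinomial-logit
    coefficients (intercept first) for classes 2..X with class 1 as the
    reference; ``naive_coef``: the uncorrected regression on modal class for
    comparison; ``factor_coef`` / ``factor_se``: (D, 1+C) least-squares
    coefficients of each posterior factor score on the covariates.
    """

    covariates: list[str]
    membership_coef: np.ndarray | None = None
    membership_se: np.ndarray | None = None
    naive_coef: np.ndarray | None = None
    corrected: bool = True
    factor_coef: np.ndarray | None = None
    factor_se: np.ndarray | None = None

    def membership_frame(self) -> pd.DataFrame:
        cols = ["intercept", *self.covariates]
        X1 = self.membership_coef.shape[0] + 1
        rows = []
        for x in range(1, X1):
            for c, name in enumerate(cols):
                rows.append(
                    dict(
                        block=f"class {x + 1}",
                        covariate=name,
                        coef=self.membership_coef[x - 1, c],
                        se=self.membership_se[x - 1, c],
                    )
                )
        return pd.DataFrame(rows)

    def factor_frame(self) -> pd.DataFrame:
        cols = ["intercept", *self.covariates]
        rows = []
        for d in range(self.factor_coef.shape[0]):
            for c, name in enumerate(cols):
                rows.append(
                    dict(
                        block=f"F{d + 1}",
                        covariate=name,
                        coef=self.factor_coef[d, c],
                        se=self.factor_se[d, c],
                    )
                )
        return pd.DataFrame(rows)


def _marginal_prior_posteriors(fit: FitResult, dataset: RankingDataset) -> PosteriorSummary:
    """Posteriors under the fitted measurement model but with the class prior
    marginalized over covariates (non-differential classification)."""
    params = fit.params.copy()
    if params.n_classes > 1:
        shares = np.clip(
            params.class_shares(dataset.membership_design()), 1e-12, None
        )
        gamma = np.zeros_like(params.gamma)
        gamma[:, 0] = np.log(shares[:-1] / shares[-1])
        params.gamma = gamma
    grid = fit.config.make_grid(params.n_effects)
    return class_posteriors(params, dataset, grid)


def _mnl_with_misclassification(W, modal, Dmat, maxiter=500):
    """Maximize Σ_i log Σ_k π_k(W_i) D[k, modal_i] over multinomial-logit
    coefficients with class 1 as reference; returns (coef, se) of shape
    (X−1, C)."""
    n, C = W.shape
    X = Dmat.shape[0]
    Dm = Dmat[:, modal].T  # (n, X): D[k, modal_i]

    def negll_grad(gvec):
        g = gvec.reshape(X - 1, C)
        logits = np.concatenate([np.zeros((n, 1)), W @ g.T], axis=1)
        logits -= logits.max(axis=1, keepdims=True)
        pi = np.exp(logits)
        pi /= pi.sum(axis=1, keepdims=True)
        L = (pi * Dm).sum(axis=1)
        r = pi * Dm / L[:, None]  # posterior over true class
        grad = ((r - pi)[:, 1:]).T @ W
        return -float(np.log(L).sum()), -grad.ravel()

    res = minimize(negll_grad, np.zeros((X - 1) * C), jac=True,
                   method="L-BFGS-B", options={"maxiter": maxiter})
    coef = res.x.reshape(X - 1, C)
    H = approx_hess(res.x, lambda t: negll_grad(t)[0])
    try:
        cov = np.linalg.inv(0.5 * (H + H.T))
        se = np.sqrt(np.clip(np.diag(cov), 0, None)).reshape(X - 1, C)
    except np.linalg.LinAlgError:  # pragma: no cover
        se = np.full((X - 1, C), np.nan)
    return coef, se


def three_step_membership(
    fit: FitResult,
    posteriors: PosteriorSummary,
    dataset: RankingDataset,
    covariates: list[str] | None = None,
    correction: str = "ml",
) -> ThreeStepResult:
    """Bias-adjusted three-step regression of class membership on covariates.

    Step 1 is the fitted measurement model (``fit``); step 2 the modal
    assignments; step 3 a multinomial logit of assigned class on covariates
    in which the known misclassification rates D[k, j] = P(assigned j | true
    k) enter the likelihood.  ``correction="none"`` gives the naive logit.
    A singular misclassification matrix triggers a warning and the naive
    fallback.
    """
    cov_names = covariates or [
        c for c in ANALYSIS_COVARIATES if c in dataset.participants.columns
    ]
    Wc = np.column_stack(
        [np.ones(dataset.n_participants), dataset.covariate_matrix(cov_names)]
    )
    X = posteriors.n_classes
    if fit is not None:
        # Step-2 assignment must not condition on covariates, or the
        # classification error becomes differential and the correction (and
        # the naive baseline) are distorted; classify under the fitted
        # measurement model with its marginalized class prior.
        posteriors = _marginal_prior_posteriors(fit, dataset)
    probs, modal = posteriors.probs, posteriors.modal

    # misclassification rates P(modal = j | true = k)
    Nk = probs.sum(axis=0)
    Dmat = np.zeros((X, X))
    for j in range(X):
        Dmat[:, j] = probs[modal == j].sum(axis=0) / Nk

    corrected = correction == "ml"
    if corrected and (np.linalg.matrix_rank(Dmat) < X):
        warnings.warn(
            "singular classification matrix; falling back to naive logit",
            RuntimeWarning,
        )
        corrected = False
    coef, se = _mnl_with_misclassification(
        Wc, modal, Dmat if corrected else np.eye(X)
    )
    naive_coef, _ = _mnl_with_misclassification(Wc, modal, np.eye(X))
    return ThreeStepResult(
        covariates=cov_names,
        membership_coef=coef,
        membership_se=se,
        naive_coef=naive_coef,
        corrected=corrected,
    )


def regress_factor_scores(
    posteriors: PosteriorSummary,
    dataset: RankingDataset,
    covariates: list[str] | None = None,
) -> ThreeStepResult:
    """One least-squares fit per posterior factor score on the covariates;
    collinear covariates are reported and dropped."""
    cov_names = list(covariates or [
        c for c in ANALYSIS_COVARIATES if c in dataset.participants.columns
    ])
    Wc = dataset.covariate_matrix(cov_names)
    keep = []
    for j in range(Wc.shape[1]):
        trial = Wc[:, keep + [j]]
        if np.linalg.matrix_rank(np.column_stack([np.ones(len(Wc)), trial])) \
                == len(keep) + 2:
            keep.append(j)
        else:
            warnings.warn(
                f"dropping collinear covariate {cov_names[j]!r}", RuntimeWarning
            )
    cov_names = [cov_names[j] for j in keep]
    Wd = sm.add_constant(Wc[:, keep])
    D = posteriors.F_mean.shape[1]
    coef = np.zeros((D, Wd.shape[1]))
    se = np.zeros_like(coef)
    for d in range(D):
        res = sm.OLS(posteriors.F_mean[:, d], Wd).fit()
        coef[d] = res.params
        se[d] = res.bse
    return ThreeStepResult(covariates=cov_names, factor_coef=coef, factor_se=se)


# ---------------------------------------------------------------------------
# concordance between models


def concordance(labels_a: np.ndarray, labels_b: np.ndarray, n_classes: int):
    """Cross-tabulate two modal assignments of the same participants and the
    agreement proportion after the best (Hungarian) class relabeling.

    Returns (crosstab, agreement, permutation): crosstab[j, k] counts
    participants assigned j by A and k by B; ``permutation``[j] is the B
    class matched to A class j.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError("assignments must cover the same participants")
    tab = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(tab, (labels_a, labels_b), 1)
    row, col = linear_sum_assignment(-tab)
    agreement = float(tab[row, col].sum() / len(labels_a))
    return tab, agreement, col


def cohort_concordance(
    fit_aggregate: FitResult,
    fits_by_group: dict,
    dataset: RankingDataset,
    group_column: str = "cohort",
):
    """Compare modal class assignments between the aggregate model and
    group-specific models with the same number of classes.

    Returns a dict per group with the cross-tab, matched agreement, and the
    pooled agreement across groups.
    """
    X = fit_aggregate.params.n_classes
    post_agg = class_posteriors(fit_aggregate, dataset)
    groups = dataset.participants[group_column].to_numpy()
    out, n_agree, n_tot = {}, 0.0, 0
    for g, fg in fits_by_group.items():
        idx = np.flatnonzero(groups == g)
        sub = dataset.subset(idx)
        post_g = class_posteriors(fg, sub)
        if fg.params.n_classes != X:
            tab = np.zeros((X, fg.params.n_classes), dtype=int)
            np.add.at(tab, (post_agg.modal[idx], post_g.modal), 1)
            out[g] = {"crosstab": tab, "agreement": None}
            continue
        tab, agree, perm = concordance(post_agg.modal[idx], post_g.modal, X)
        out[g] = {"crosstab": tab, "agreement": agree, "permutation": perm}
        n_agree += agree * len(idx)
        n_tot += len(idx)
    if n_tot:
        out["overall_agreement"] = n_agree / n_tot
    return out
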
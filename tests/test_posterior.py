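"""Posterior class membership, factor scores, individual preferences,
three-step correction, and concordance."""

import numpy as np
import pytest

from relclogit import (
    RELCLParams,
    class_posteriors,
    concordance,
    gauss_hermite_grid,
    individual_preferences,
    regress_factor_scores,
    three_step_membership,
)
from relclogit.posterior import PosteriorSummary, _mnl_with_misclassification


class TestClassPosteriors:
    def test_single_class_degenerate(self, small_scheme, dataset_2c1d, truth_2c1d):
        ds, _ = dataset_2c1d
        sub = ds.subset(np.arange(30))
        p = RELCLParams(
            small_scheme, truth_2c1d.beta[:1],
            np.zeros((0, small_scheme.n_contrasts)), np.zeros((0, 0)),
        )
        post = class_posteriors(p, sub, gauss_hermite_grid(0))
        np.testing.assert_allclose(post.probs, 1.0)
        assert np.all(post.modal == 0)
        np.testing.assert_allclose(post.classification_matrix, [[1.0]])

    def test_no_loadings_zero_scores(self, dataset_3c2d, truth_3c2d):
        ds, _ = dataset_3c2d
        p = truth_3c2d.copy()
        p.lam = np.zeros_like(p.lam)
        post = class_posteriors(p, ds.subset(np.arange(50)),
                                gauss_hermite_grid(2, 5))
        np.testing.assert_allclose(post.F_mean, 0.0, atol=1e-10)

    def test_normalization_and_row_stochasticity(self, dataset_3c2d, truth_3c2d):
        ds, _ = dataset_3c2d
        post = class_posteriors(truth_3c2d, ds, gauss_hermite_grid(2, 5))
        np.testing.assert_allclose(post.probs.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(
            post.classification_matrix.sum(axis=1), 1.0, atol=1e-12
        )

    def test_modal_recovers_ground_truth(self, dataset_3c2d, truth_3c2d):
        """With well-separated classes, modal assignment matches the
        generating class for at least 90% of participants."""
        ds, gt = dataset_3c2d
        post = class_posteriors(truth_3c2d, ds, gauss_hermite_grid(2, 7))
        assert (post.modal == gt.classes).mean() >= 0.90

    def test_factor_scores_track_truth(self, dataset_3c2d, truth_3c2d):
        ds, gt = dataset_3c2d
        post = class_posteriors(truth_3c2d, ds, gauss_hermite_grid(2, 7))
        for d in range(2):
            r = np.corrcoef(post.F_mean[:, d], gt.F[:, d])[0, 1]
            assert r > 0.5


class TestIndividualPreferences:
    def test_no_loadings_class_profiles(self, dataset_3c2d, truth_3c2d):
        ds, _ = dataset_3c2d
        p = truth_3c2d.copy()
        p.lam = np.zeros_like(p.lam)
        post = class_posteriors(p, ds.subset(np.arange(100)),
                                gauss_hermite_grid(2, 5))
        vals = individual_preferences(p, post)
        for x in range(3):
            rows = vals[post.modal == x]
            if len(rows):
                assert np.ptp(rows, axis=0).max() < 1e-12
                np.testing.assert_allclose(rows[0], p.expanded_beta()[x])

    def test_values_sum_to_zero_within_attribute(self, small_scheme,
                                                 dataset_3c2d, truth_3c2d):
        ds, _ = dataset_3c2d
        post = class_posteriors(truth_3c2d, ds.subset(np.arange(100)),
                                gauss_hermite_grid(2, 5))
        vals = individual_preferences(truth_3c2d, post)
        for sl in small_scheme.level_slices():
            np.testing.assert_allclose(vals[:, sl].sum(axis=1), 0, atol=1e-10)

    def test_within_class_spread_ordered_by_loading(self, small_scheme,
                                                    dataset_3c2d, truth_3c2d):
        """Levels with larger |expanded loading| show wider within-class
        spread of individual preference values."""
        ds, _ = dataset_3c2d
        post = class_posteriors(truth_3c2d, ds, gauss_hermite_grid(2, 7))
        vals = individual_preferences(truth_3c2d, post)
        lam_exp = np.abs(truth_3c2d.expanded_lam()).sum(axis=0)
        modal0 = vals[post.modal == 0]
        sds = modal0.std(axis=0)
        order = np.argsort(lam_exp)
        # rank correlation between |loading| and within-class SD
        from scipy.stats import spearmanr

        rho, _ = spearmanr(lam_exp, sds)
        assert rho > 0.7
        assert sds[order[-1]] > sds[order[0]]


def _synthetic_posterior(n, X, gamma, rng, accuracy=0.8):
    """Generative three-step testbed with genuine posteriors.

    True classes follow a multinomial logit on one binary covariate (class 1
    is the reference; ``gamma`` rows are intercept+slope for classes 2..X).
    An error-prone class indicator is drawn from a symmetric confusion kernel
    with the given accuracy, and posteriors are computed by Bayes' rule under
    the marginal class prior — exactly what a covariate-free measurement
    model would deliver.  Returns (posterior summary, covariate, true class).
    """
    cov = (rng.random(n) < 0.5).astype(float)
    logits = np.column_stack([np.zeros(n)] + [
        gamma[k, 0] + gamma[k, 1] * cov for k in range(X - 1)
    ])
    p = np.exp(logits - logits.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    true = (p.cumsum(axis=1) < rng.random(n)[:, None]).sum(axis=1)
    C = accuracy * np.eye(X) + (1 - accuracy) / X * np.ones((X, X))
    C /= C.sum(axis=1, keepdims=True)
    signal = (C[true].cumsum(axis=1) < rng.random(n)[:, None]).sum(axis=1)
    prior = p.mean(axis=0)
    post = prior[None, :] * C[:, signal].T
    post /= post.sum(axis=1, keepdims=True)
    modal = post.argmax(axis=1)
    cmat = np.empty((X, X))
    for j in range(X):
        sel = modal == j
        cmat[j] = post[sel].mean(axis=0) if sel.any() else np.eye(X)[j]
    summary = PosteriorSummary(
        probs=post, modal=modal, F_mean=np.zeros((n, 0)),
        F_sd=np.zeros((n, 0)), classification_matrix=cmat,
    )
    return summary, cov, true


class TestThreeStep:
    def test_perfect_classification_equals_naive(self, dataset_2c1d):
        """When posteriors are exactly 0/1 the estimated misclassification
        matrix is the identity and the correction is a no-op."""
        ds, gt = dataset_2c1d
        n = ds.n_participants
        true = gt.classes
        post = PosteriorSummary(
            probs=np.eye(2)[true], modal=true,
            F_mean=np.zeros((n, 0)), F_sd=np.zeros((n, 0)),
            classification_matrix=np.eye(2),
        )
        res = three_step_membership(None, post, ds, covariates=["cohort"])
        assert res.corrected
        np.testing.assert_allclose(res.membership_coef, res.naive_coef, atol=1e-6)

    def test_corrected_recovers_slope_naive_attenuates(self):
        """With noisy class assignment, the naive logit shrinks the covariate
        effect toward zero while the bias-adjusted estimator recovers it."""
        rng = np.random.default_rng(42)
        n, X = 2000, 2
        slope = 1.0
        gamma = np.array([[0.2, slope]])
        post, cov, true = _synthetic_posterior(n, X, gamma, rng, accuracy=0.7)
        W = np.column_stack([np.ones(n), cov])
        Dmat = np.zeros((X, X))
        Nk = post.probs.sum(axis=0)
        for j in range(X):
            Dmat[:, j] = post.probs[post.modal == j].sum(axis=0) / Nk
        corrected, _ = _mnl_with_misclassification(W, post.modal, Dmat)
        naive, _ = _mnl_with_misclassification(W, post.modal, np.eye(X))
        assert abs(corrected[0, 1] - slope) <= 0.25
        assert abs(naive[0, 1]) < abs(corrected[0, 1])

    def test_type_one_error_controlled(self):
        """Zero covariate effect: corrected slope within ±2·SE of 0 in at
        least 90% of replicates."""
        hits = 0
        for rep in range(20):
            rng = np.random.default_rng(900 + rep)
            n, X = 800, 2
            gamma = np.array([[0.3, 0.0]])
            post, cov, true = _synthetic_posterior(n, X, gamma, rng, accuracy=0.7)
            W = np.column_stack([np.ones(n), cov])
            Dmat = np.zeros((X, X))
            Nk = post.probs.sum(axis=0)
            for j in range(X):
                Dmat[:, j] = post.probs[post.modal == j].sum(axis=0) / Nk
            coef, se = _mnl_with_misclassification(W, post.modal, Dmat)
            hits += abs(coef[0, 1]) <= 2 * se[0, 1]
        assert hits >= 18

    def test_bias_shrinks_with_separation(self):
        """Corrected-estimator bias decreases monotonically as posterior
        entropy shrinks (better-separated classes)."""
        slope = 1.0
        biases = []
        for accuracy in (0.55, 0.75, 0.95):
            errs = []
            for rep in range(10):
                rng = np.random.default_rng(50 + rep)
                post, cov, true = _synthetic_posterior(
                    2500, 2, np.array([[0.2, slope]]), rng, accuracy=accuracy
                )
                W = np.column_stack([np.ones(len(cov)), cov])
                Dmat = np.zeros((2, 2))
                Nk = post.probs.sum(axis=0)
                for j in range(2):
                    Dmat[:, j] = post.probs[post.modal == j].sum(axis=0) / Nk
                coef, _ = _mnl_with_misclassification(W, post.modal, Dmat)
                errs.append(coef[0, 1] - slope)
            biases.append(abs(np.mean(errs)))
        assert biases[0] >= biases[1] >= biases[2]

    def test_full_pipeline_interface(self, fit_2c1d, dataset_2c1d):
        ds, _ = dataset_2c1d
        post = class_posteriors(fit_2c1d, ds)
        res = three_step_membership(fit_2c1d, post, ds)
        assert res.membership_coef.shape == (1, 7)
        assert res.corrected
        frame = res.membership_frame()
        assert {"block", "covariate", "coef", "se"} <= set(frame.columns)


class TestRegressFactorScores:
    def test_zero_scores_zero_coefficients(self, dataset_2c1d):
        ds, _ = dataset_2c1d
        n = ds.n_participants
        post = PosteriorSummary(
            probs=np.ones((n, 1)), modal=np.zeros(n, dtype=int),
            F_mean=np.zeros((n, 1)), F_sd=np.zeros((n, 1)),
            classification_matrix=np.eye(1),
        )
        res = regress_factor_scores(post, ds)
        np.testing.assert_allclose(res.factor_coef, 0.0, atol=1e-12)

    def test_injected_dependence_recovered(self, dataset_2c1d):
        ds, _ = dataset_2c1d
        rng = np.random.default_rng(77)
        n = ds.n_participants
        age = ds.participants["age"].to_numpy(dtype=float)
        scores = (0.05 * age + 0.3 * rng.standard_normal(n))[:, None]
        post = PosteriorSummary(
            probs=np.ones((n, 1)), modal=np.zeros(n, dtype=int),
            F_mean=scores, F_sd=np.zeros((n, 1)),
            classification_matrix=np.eye(1),
        )
        res = regress_factor_scores(post, ds)
        age_ix = 1 + res.covariates.index("age")
        assert abs(res.factor_coef[0, age_ix] - 0.05) <= 0.01

    def test_residuals_orthogonal_to_covariates(self, fit_2c1d, dataset_2c1d):
        ds, _ = dataset_2c1d
        post = class_posteriors(fit_2c1d, ds)
        res = regress_factor_scores(post, ds)
        import statsmodels.api as sm

        W = sm.add_constant(ds.covariate_matrix(res.covariates))
        resid = post.F_mean[:, 0] - W @ res.factor_coef[0]
        np.testing.assert_allclose(W.T @ resid, 0, atol=1e-6)

    def test_collinear_covariate_dropped(self, dataset_2c1d):
        ds, _ = dataset_2c1d
        ds2 = ds.subset(np.arange(ds.n_participants))
        ds2.participants["age_copy"] = ds2.participants["age"]
        n = ds2.n_participants
        post = PosteriorSummary(
            probs=np.ones((n, 1)), modal=np.zeros(n, dtype=int),
            F_mean=np.zeros((n, 1)), F_sd=np.zeros((n, 1)),
            classification_matrix=np.eye(1),
        )
        with pytest.warns(RuntimeWarning, match="collinear"):
            res = regress_factor_scores(
                post, ds2, covariates=["age", "age_copy", "married"]
            )
        assert "age_copy" not in res.covariates


class TestConcordance:
    def test_self_agreement_is_one(self, dataset_3c2d, truth_3c2d):
        ds, _ = dataset_3c2d
        post = class_posteriors(truth_3c2d, ds.subset(np.arange(200)),
                                gauss_hermite_grid(2, 5))
        _, agree, _ = concordance(post.modal, post.modal, 3)
        assert agree == 1.0

    def test_random_assignments_chance_level(self):
        rng = np.random.default_rng(123)
        a = rng.integers(0, 4, size=2000)
        b = rng.integers(0, 4, size=2000)
        _, agree, _ = concordance(a, b, 4)
        assert abs(agree - 0.25) <= 0.05

    def test_crosstab_margins_match_class_sizes(self):
        rng = np.random.default_rng(124)
        a = rng.integers(0, 3, size=500)
        b = rng.integers(0, 3, size=500)
        tab, _, _ = concordance(a, b, 3)
        np.testing.assert_array_equal(tab.sum(axis=1), np.bincount(a, minlength=3))
        np.testing.assert_array_equal(tab.sum(axis=0), np.bincount(b, minlength=3))

    def test_relabeled_assignments_fully_recovered(self):
        rng = np.random.default_rng(125)
        a = rng.integers(0, 3, size=400)
        b = (a + 1) % 3  # pure relabeling
        _, agree, perm = concordance(a, b, 3)
        assert agree == 1.0
        np.testing.assert_array_equal(perm, [1, 2, 0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            concordance(np.zeros(5, dtype=int), np.zeros(6, dtype=int), 2)

    def test_cohort_concordance_with_identical_models(self, fit_2c1d,
                                                      dataset_2c1d):
        """Comparing the aggregate model with itself on each cohort gives
        full agreement and cohort-sized cross-tab margins."""
        from relclogit import cohort_concordance

        ds, _ = dataset_2c1d
        conc = cohort_concordance(fit_2c1d, {0: fit_2c1d, 1: fit_2c1d}, ds)
        assert conc["overall_agreement"] == pytest.approx(1.0)
        n0 = (ds.participants["cohort"] == 0).sum()
        assert conc[0]["crosstab"].sum() == n0
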
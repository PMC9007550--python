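"""Estimation: EM monotonicity, oracle equivalence, multi-start stability,
canonical form, recovery with standard-error coverage, and the BIC grid."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize

from relclogit import (
    RELCLParams,
    align_parameters,
    canonicalize,
    draw_participants,
    em_step,
    fit,
    fit_grid,
    gauss_hermite_grid,
    init_params,
    marginal_loglik,
    simulate_dataset,
)
from relclogit.estimation import _order_bounds
from relclogit.scheme import Attribute, AttributeScheme, effects_code


class TestInitParams:
    def test_deterministic_and_distinct(self, small_scheme):
        a = init_params(small_scheme, 3, 2, np.random.default_rng(4))
        b = init_params(small_scheme, 3, 2, np.random.default_rng(4))
        np.testing.assert_array_equal(a.beta, b.beta)
        seen = {
            init_params(small_scheme, 3, 2, np.random.default_rng(s)).beta.tobytes()
            for s in range(16)
        }
        assert len(seen) == 16

    def test_single_class_empty_gamma(self, small_scheme):
        p = init_params(small_scheme, 1, 0, np.random.default_rng(0))
        assert p.gamma.size == 0
        assert p.lam.shape == (0, small_scheme.n_contrasts)

    def test_loadings_respect_mask(self, small_scheme):
        p = init_params(small_scheme, 2, 2, np.random.default_rng(1))
        assert np.all(p.lam[~p.domain_mask] == 0)


class TestEMStep:
    def test_loglik_nondecreasing_over_50_steps(self, small_scheme, small_design,
                                                truth_2c1d):
        ds, _ = simulate_dataset(
            small_scheme, small_design, truth_2c1d, n=150,
            rng=np.random.default_rng(31),
        )
        grid = gauss_hermite_grid(1, 5)
        params = init_params(small_scheme, 2, 1, np.random.default_rng(0))
        lls = []
        for _ in range(50):
            params, ll = em_step(params, ds, grid, mstep_maxiter=6)
            lls.append(ll)
        diffs = np.diff(lls)
        assert np.all(diffs >= -1e-8)

    def test_stationary_point_small_change(self, small_scheme, small_design,
                                           truth_2c1d, fast_config):
        ds, _ = simulate_dataset(
            small_scheme, small_design, truth_2c1d, n=200,
            rng=np.random.default_rng(32),
        )
        r = fit(ds, small_scheme, 2, 1, fast_config(seed=3))
        grid = gauss_hermite_grid(1, 7)
        ll0 = marginal_loglik(r.params, ds, grid)
        stepped, _ = em_step(r.params, ds, grid, mstep_maxiter=25)
        ll1 = marginal_loglik(stepped, ds, grid)
        assert 0 <= ll1 - ll0 < 1e-3


class TestConditionalLogitOracle:
    def test_single_class_matches_direct_optimizer(self, small_scheme,
                                                   small_design, truth_2c1d,
                                                   fast_config):
        """X=1, D=0 reduces to a plain exploded conditional logit; compare
        with an independent brute-force likelihood optimized numerically."""
        ds, _ = simulate_dataset(
            small_scheme, small_design, truth_2c1d, n=150,
            rng=np.random.default_rng(33),
        )
        r = fit(ds, small_scheme, 1, 0, fast_config(order_constraint=False))

        codes = [
            np.array([effects_code(l, a.n_levels) for l in range(1, a.n_levels + 1)])
            for a in small_scheme.attributes
        ]

        def brute_nll(b):
            total = 0.0
            for i in range(ds.n_participants):
                for t in range(ds.n_tasks):
                    utils = []
                    for m in range(3):
                        z = np.concatenate(
                            [codes[j][ds.levels[i, t, m, j] - 1]
                             for j in range(3)]
                        )
                        utils.append(float(z @ b))
                    e = [math.exp(u) for u in utils]
                    f, s = ds.first[i, t], ds.second[i, t]
                    total += math.log(e[f] / sum(e))
                    total += math.log(e[s] / (sum(e) - e[f]))
            return -total

        res = minimize(brute_nll, np.zeros(5), method="BFGS")
        np.testing.assert_allclose(r.params.beta[0], res.x, atol=1e-4)


class TestFit:
    def test_recovery_with_se_coverage(self, small_scheme, small_design,
                                       truth_2c1d, fast_config):
        """Parameter recovery over seeded replicates: small mean absolute
        bias of expanded β and ±2·SE coverage in the nominal range."""
        biases, covered, total = [], 0, 0
        for rep in range(6):
            rng = np.random.default_rng(300 + rep)
            parts = draw_participants(600, rng=rng, n_blocks=1)
            ds, _ = simulate_dataset(
                small_scheme, small_design, truth_2c1d, participants=parts, rng=rng
            )
            r = fit(ds, small_scheme, 2, 1,
                    fast_config(seed=rep, standard_errors=True))
            aligned = align_parameters(r.params, truth_2c1d)
            err = aligned.expanded_beta() - truth_2c1d.expanded_beta()
            biases.append(err)
            # match SE rows to the aligned class order
            perm = [
                int(np.argmin(np.abs(r.params.beta - aligned.beta[x]).sum(axis=1)))
                for x in range(2)
            ]
            se = r.se_beta_expanded[perm]
            covered += int((np.abs(err) <= 2 * se).sum())
            total += err.size
        mean_abs_bias = np.abs(np.mean(biases, axis=0)).mean()
        assert mean_abs_bias <= 0.1
        assert 0.85 <= covered / total <= 1.0

    def test_multistart_stability(self, dataset_2c1d, small_scheme, fast_config):
        """A wider multi-start reproduces the best log-likelihood found by a
        narrow one (global optimum reached)."""
        ds, _ = dataset_2c1d
        ll_narrow = fit(ds, small_scheme, 2, 1, fast_config(n_starts=2, seed=0)).loglik
        ll_wide = fit(ds, small_scheme, 2, 1, fast_config(n_starts=6, seed=1)).loglik
        assert abs(ll_wide - ll_narrow) <= 1e-3

    def test_single_participant_converges(self, small_scheme, small_design,
                                          truth_2c1d, fast_config):
        ds, _ = simulate_dataset(
            small_scheme, small_design, truth_2c1d, n=None,
            cohort_counts=(1, 0), rng=np.random.default_rng(5),
        )
        r = fit(ds, small_scheme, 1, 0, fast_config(n_starts=1))
        assert np.all(np.isfinite(r.params.beta))

    def test_classes_ordered_by_size(self, fit_2c1d, dataset_2c1d):
        ds, _ = dataset_2c1d
        shares = fit_2c1d.params.class_shares(ds.membership_design())
        assert np.all(np.diff(shares) <= 1e-9)

    def test_bic_formula(self, fit_2c1d, dataset_2c1d):
        ds, _ = dataset_2c1d
        expected = -2 * fit_2c1d.loglik + fit_2c1d.n_params * np.log(
            ds.n_participants
        )
        assert fit_2c1d.bic == pytest.approx(expected)
        assert fit_2c1d.n_params == 2 * 5 + 3 + 2

    def test_empty_dataset_rejected(self, dataset_2c1d, small_scheme, fast_config):
        ds, _ = dataset_2c1d
        with pytest.raises(ValueError):
            fit(ds.subset(np.arange(0)), small_scheme, 1, 0, fast_config())


class TestCanonicalize:
    def test_idempotent(self, truth_3c2d):
        once = canonicalize(truth_3c2d)
        twice = canonicalize(once)
        np.testing.assert_allclose(once.beta, twice.beta, atol=1e-12)
        np.testing.assert_allclose(once.lam, twice.lam, atol=1e-12)
        np.testing.assert_allclose(once.gamma, twice.gamma, atol=1e-12)

    def test_preserves_likelihood(self, dataset_3c2d, truth_3c2d):
        ds, _ = dataset_3c2d
        sub = ds.subset(np.arange(80))
        base = marginal_loglik(truth_3c2d, sub, n_nodes=5)
        canon = canonicalize(truth_3c2d, sub.membership_design())
        assert marginal_loglik(canon, sub, n_nodes=5) == pytest.approx(
            base, abs=1e-8
        )

    def test_dominant_loading_positive(self, truth_3c2d):
        canon = canonicalize(truth_3c2d)
        lam_exp = canon.expanded_lam()
        for d in range(canon.n_effects):
            assert lam_exp[d, np.argmax(np.abs(lam_exp[d]))] > 0


class TestOrderConstraint:
    def test_bounds_on_ordered_two_level_attribute(self):
        scheme = AttributeScheme(
            attributes=(
                Attribute("a", ("1", "2", "3"), domain=1),
                Attribute("avail", ("weekdays", "everyday"), domain=1,
                          ordered=True),
            )
        )
        p = init_params(scheme, 2, 0, np.random.default_rng(0))
        bounds = _order_bounds(p)
        # the ordered attribute's contrast is column 2 within each class block
        assert bounds[2] == (None, 0.0)
        assert bounds[3 + 2] == (None, 0.0)
        assert bounds[0] == (None, None)

    def test_constraint_enforced_in_fit(self, fast_config):
        scheme = AttributeScheme(
            attributes=(
                Attribute("a", ("1", "2", "3"), domain=1),
                Attribute("avail", ("weekdays", "everyday"), domain=1,
                          ordered=True),
            )
        )
        # generating truth violates the constraint: weekdays preferred
        truth = RELCLParams(
            scheme, np.array([[0.5, -0.3, 0.8]]),
            np.zeros((0, scheme.n_contrasts)), np.zeros((0, 0)),
        )
        from relclogit import generate_design

        rng = np.random.default_rng(40)
        des = generate_design(scheme, 12, 1, 3, rng)
        ds, _ = simulate_dataset(scheme, des, truth, n=200, rng=rng)
        r = fit(ds, scheme, 1, 0, fast_config(n_starts=1))
        # boundary solution: expanded 'everyday' coefficient is >= 0
        assert r.params.expanded_beta()[0, -1] >= -1e-9


class TestFitGrid:
    def test_grid_selects_generating_model(self, small_scheme, small_design,
                                           truth_2c1d, fast_config):
        rng = np.random.default_rng(55)
        parts = draw_participants(400, rng=rng, n_blocks=1)
        ds, _ = simulate_dataset(
            small_scheme, small_design, truth_2c1d, participants=parts, rng=rng
        )
        df = fit_grid(ds, small_scheme, range(1, 4), range(0, 2),
                      fast_config(seed=2))
        assert len(df) == 6
        best = df.loc[df["is_best"]].iloc[0]
        assert (best["n_classes"], best["n_effects"]) == (2, 1)

    def test_loglik_nondecreasing_in_classes(self, small_scheme, small_design,
                                             truth_2c1d, fast_config):
        rng = np.random.default_rng(56)
        ds, _ = simulate_dataset(small_scheme, small_design, truth_2c1d,
                                 n=300, rng=rng)
        df = fit_grid(ds, small_scheme, range(1, 4), range(0, 1),
                      fast_config(seed=3))
        lls = df.sort_values("n_classes")["loglik"].to_numpy()
        assert np.all(np.diff(lls) >= -0.5)  # optimizer noise tolerance

    def test_d0_column_matches_plain_fit(self, small_scheme, small_design,
                                         truth_2c1d, fast_config):
        rng = np.random.default_rng(57)
        ds, _ = simulate_dataset(small_scheme, small_design, truth_2c1d,
                                 n=200, rng=rng)
        cfg = fast_config(seed=4)
        df = fit_grid(ds, small_scheme, range(2, 3), range(0, 1), cfg)
        direct = fit(ds, small_scheme, 2, 0, cfg)
        assert df.iloc[0]["loglik"] == pytest.approx(direct.loglik, abs=1e-6)

    def test_cell_failure_recorded_not_raised(self, dataset_2c1d, small_scheme,
                                              fast_config, monkeypatch):
        ds, _ = dataset_2c1d
        import relclogit.estimation as est

        orig = est.fit

        def flaky(dataset, scheme=None, n_classes=1, n_effects=0, config=None):
            if n_classes == 2:
                raise RuntimeError("boom")
            return orig(dataset, scheme, n_classes, n_effects, config)

        monkeypatch.setattr(est, "fit", flaky)
        df = est.fit_grid(ds.subset(np.arange(100)), small_scheme,
                          range(1, 3), range(0, 1), fast_config())
        assert (df["error"] != "").sum() == 1
        assert df["bic"].notna().sum() == 1
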
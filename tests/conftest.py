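"""Shared fixtures: compact schemes, designs and simulated datasets.

The default test scenario is a scaled-down version of the study conditions:
3 latent classes, 2 domain random effects, well-separated class profiles
(coefficient gaps >= 1.0) and n = 1000 participants, which keeps estimation
well-identified at unit-test cost.
"""

from __future__ import annotations

import numpy as np
import pytest

from relclogit import (
    AttributeScheme,
    FitConfig,
    RELCLParams,
    draw_participants,
    generate_design,
    simulate_dataset,
)
from relclogit.scheme import Attribute


@pytest.fixture(scope="session")
def small_scheme() -> AttributeScheme:
    """Three attributes (3+3+2 levels), two preference domains."""
    return AttributeScheme(
        attributes=(
            Attribute("quality", ("low", "medium", "high"), domain=1),
            Attribute("venue", ("clinic", "home", "mobile"), domain=2),
            Attribute("cost", ("free", "paid"), domain=1),
        )
    )


@pytest.fixture(scope="session")
def small_design(small_scheme):
    rng = np.random.default_rng(2024)
    return generate_design(small_scheme, n_tasks=12, n_blocks=1, n_alts=3, rng=rng)


@pytest.fixture(scope="session")
def truth_2c1d(small_scheme) -> RELCLParams:
    """2-class, 1-random-effect generating truth with separation >= 1.0."""
    beta = np.array(
        [[1.0, -0.5, 0.8, -0.6, 0.5],
         [-0.8, 0.7, -0.9, 0.9, -0.5]]
    )
    lam = np.array([[0.6, -0.3, 0.0, 0.0, 0.3]])  # domain-1 contrasts only
    lam = np.where(small_scheme.domain_mask(1), lam, 0.0)
    return RELCLParams(small_scheme, beta, lam, np.array([[0.3, -0.4]]))


@pytest.fixture(scope="session")
def truth_3c2d(small_scheme) -> RELCLParams:
    """Default scenario truth: 3 classes, 2 effects, gaps >= 1.0."""
    beta = np.array(
        [[1.2, -0.6, 0.9, -0.7, 0.6],
         [-1.0, 0.8, -0.8, 0.9, -0.6],
         [0.1, 1.1, 0.2, -1.2, 1.0]]
    )
    lam = np.array(
        [[0.6, -0.3, 0.0, 0.0, 0.4],   # domain 1: quality + cost contrasts
         [0.0, 0.0, 0.7, 0.2, 0.0]]    # domain 2: venue contrasts
    )
    mask = small_scheme.domain_mask(2)
    lam = np.where(mask, lam, 0.0)
    gamma = np.array([[0.5, -0.6], [-0.2, 0.5]])
    return RELCLParams(small_scheme, beta, lam, gamma)


@pytest.fixture(scope="session")
def dataset_3c2d(small_scheme, small_design, truth_3c2d):
    """n=1000 participants simulated from the default scenario."""
    rng = np.random.default_rng(7)
    parts = draw_participants(1000, rng=rng, n_blocks=1)
    return simulate_dataset(
        small_scheme, small_design, truth_3c2d, participants=parts, rng=rng
    )


@pytest.fixture(scope="session")
def dataset_2c1d(small_scheme, small_design, truth_2c1d):
    """n=800 participants simulated from the 2-class / 1-effect truth."""
    rng = np.random.default_rng(13)
    parts = draw_participants(800, rng=rng, n_blocks=1)
    return simulate_dataset(
        small_scheme, small_design, truth_2c1d, participants=parts, rng=rng
    )


@pytest.fixture()
def fast_config():
    """Estimation settings scaled for tests: a short EM warm start and a
    longer exact-gradient quasi-Newton phase reach the same optima as the
    full schedule at a fraction of the cost on these problem sizes."""

    def make(**kw) -> FitConfig:
        base = dict(
            n_starts=3, seed=0, em_iterations=8, mstep_maxiter=6,
            newton_iterations=200, tol=1e-4,
        )
        base.update(kw)
        return FitConfig(**base)

    return make


@pytest.fixture(scope="session")
def fit_2c1d(small_scheme, dataset_2c1d):
    """One fitted 2-class / 1-effect model shared across test modules."""
    from relclogit import fit

    ds, _ = dataset_2c1d
    cfg = FitConfig(n_starts=3, seed=5, em_iterations=8, mstep_maxiter=6,
                    newton_iterations=200)
    return fit(ds, small_scheme, 2, 1, cfg)
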
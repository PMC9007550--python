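"""Synthetic ranked-choice data with latent class and random-effect structure.

The generator draws participants with realistic covariates, assigns each to a
latent preference class by a covariate-dependent multinomial logit, draws
independent standard-normal domain random-effect scores, and simulates
sequential best / second-best choices from the exploded logit implied by the
class-specific utilities.  No Gumbel errors are drawn explicitly: the two
ranking stages are fresh logit draws from the same deterministic utilities,
which is exactly the data-generating process the exploded-logit likelihood
describes.

The default scenario reproduces the conditions of the HIV-testing preference
study the model was developed for: 740 participants (300 female barworkers,
440 male mountain porters), 12 tasks of 3 alternatives from a 120-task /
10-block design, 8 preference classes and 3 domain random effects with the
published coefficient profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import RankingDataset, code_levels
from .design import ChoiceDesign, randomize_for_participant
from .params import RELCLParams
from .scheme import AttributeScheme, hiv_testing_scheme

__all__ = [
    "GroundTruth",
    "draw_participants",
    "assign_classes",
    "simulate_ranking",
    "simulate_dataset",
    "study_params",
    "study_covariate_config",
    "STUDY_N_BARWORKERS",
    "STUDY_N_PORTERS",
]

STUDY_N_BARWORKERS = 300
STUDY_N_PORTERS = 440

#: Covariate marginals of the two study cohorts (keyed by cohort code):
#: age ~ Normal(mean, sd) truncated to 18..49; binary covariates Bernoulli;
#: HIV-testing history multinomial over (never, once, more than once).
STUDY_COVARIATE_CONFIG = {
    0: {  # female barworkers
        "age_mean": 29.7, "age_sd": 7.61,
        "married": 0.318, "secondary_education": 0.579,
        "tests": (0.053, 0.137, 0.810),
    },
    1: {  # male mountain porters
        "age_mean": 31.4, "age_sd": 6.71,
        "married": 0.656, "secondary_education": 0.446,
        "tests": (0.200, 0.200, 0.600),
    },
}

# Published 8-class coefficient profile (expanded per-level values) for the
# HIV-testing scheme; rows follow hiv_testing_scheme() level order, columns
# are classes 1..8 (transposed below).
_STUDY_BETA_ROWS = [
    # venue: home, health facility, VCT center
    [-1.34, -1.06, -1.18, -1.19, -0.07, -0.84, 1.26, -0.87],
    [1.65, 1.45, 1.87, 0.16, 0.17, 1.30, -0.48, -0.78],
    [-0.31, -0.39, -0.69, 1.03, -0.10, -0.46, -0.78, 1.65],
    # availability: weekdays only, every day
    [-0.15, -0.72, -1.09, -0.35, 0.00, -0.33, -0.61, -1.13],
    [0.15, 0.72, 1.09, 0.35, 0.00, 0.33, 0.61, 1.13],
    # sample type: arm, finger, mouth
    [0.50, -0.66, 1.45, 0.64, -0.55, 0.59, 0.26, 1.29],
    [-0.17, 1.55, -0.81, -0.14, 0.87, -0.15, -0.15, -0.42],
    [-0.33, -0.89, -0.64, -0.50, -0.32, -0.44, -0.11, -0.87],
    # additional services: HIV test only, health check, STI examination
    [-0.66, -1.09, -1.57, -0.71, -0.45, -1.18, -1.04, -2.01],
    [-0.02, 0.87, 2.07, 0.44, -0.22, 0.96, 1.10, 2.68],
    [0.68, 0.22, -0.51, 0.26, 0.67, 0.22, -0.06, -0.67],
    # counseling/notification compound:
    # 1-on-1 self, 1-on-1 provider, group self, group provider, couples auto
    [0.32, -0.08, 0.07, 0.37, 0.38, -0.72, -0.30, -0.58],
    [-0.18, -0.22, -0.62, -0.22, 0.63, -0.72, -0.25, 0.35],
    [-0.14, -0.86, -0.63, -0.44, -0.43, 0.76, -0.30, -1.09],
    [-0.68, -0.63, -1.18, -0.87, -0.29, 0.92, -0.34, -0.79],
    [0.69, 1.80, 2.36, 1.17, -0.28, -0.24, 1.19, 2.11],
]

# Published domain loadings (expanded per-level, same row order): domain 1 =
# privacy & confidentiality, 2 = invasiveness & accuracy, 3 = accessibility
# & value; zero where the level's attribute is outside the domain.
_STUDY_LAMBDA_ROWS = {
    1: [-0.168, 0.103, 0.065, 0, 0, 0, 0, 0, 0, 0, 0,
        0.735, 0.786, 0.175, 0.059, -1.755],
    2: [0, 0, 0, 0, 0, 0.911, 0.114, -1.025, 0, 0, 0, 0, 0, 0, 0, 0],
    3: [0, 0, 0, 0.408, -0.408, 0, 0, 0, 0.049, 0.391, -0.440, 0, 0, 0, 0, 0],
}

#: class shares by cohort (classes 1..8), used to derive the membership logit
_STUDY_CLASS_SHARES = {
    0: np.array([0.200, 0.180, 0.154, 0.138, 0.126, 0.097, 0.046, 0.061]),
    1: np.array([0.183, 0.191, 0.122, 0.121, 0.125, 0.103, 0.095, 0.061]),
}


def study_covariate_config() -> dict:
    return {k: dict(v) for k, v in STUDY_COVARIATE_CONFIG.items()}


def _gamma_from_shares(shares0: np.ndarray, shares1: np.ndarray) -> np.ndarray:
    """Membership logit coefficients (intercept, cohort slope) per non-
    reference class reproducing the given per-cohort class shares exactly."""
    s0 = shares0 / shares0.sum()
    s1 = shares1 / shares1.sum()
    icpt = np.log(s0[:-1] / s0[-1])
    slope = np.log(s1[:-1] / s1[-1]) - icpt
    return np.column_stack([icpt, slope])


def study_params(scheme: AttributeScheme | None = None) -> RELCLParams:
    """The 8-class / 3-random-effect generating parameters of the default
    scenario (published coefficient profile; membership logit matching the
    per-cohort class shares)."""
    if scheme is None:
        scheme = hiv_testing_scheme()
    beta_exp = np.array(_STUDY_BETA_ROWS, dtype=float).T  # (8, 16)
    lam_exp = np.array(
        [_STUDY_LAMBDA_ROWS[d] for d in (1, 2, 3)], dtype=float
    )
    gamma = _gamma_from_shares(_STUDY_CLASS_SHARES[0], _STUDY_CLASS_SHARES[1])
    return RELCLParams.from_expanded(scheme, beta_exp, lam_exp, gamma)


def draw_participants(
    n: int | None = None,
    covariate_config: dict | None = None,
    rng: np.random.Generator | None = None,
    cohort_counts: tuple[int, int] | None = None,
    n_blocks: int = 10,
) -> pd.DataFrame:
    """Draw a participant table with covariates from per-cohort marginals.

    ``cohort_counts`` fixes the exact number per cohort (default: the study's
    300/440 split scaled to n); blocks are assigned round-robin.
    """
    if rng is None:
        rng = np.random.default_rng()
    if cohort_counts is None:
        if n is None:
            cohort_counts = (STUDY_N_BARWORKERS, STUDY_N_PORTERS)
        else:
            n0 = int(round(n * STUDY_N_BARWORKERS / (STUDY_N_BARWORKERS + STUDY_N_PORTERS)))
            cohort_counts = (n0, n - n0)
    n = sum(cohort_counts)
    if n < 1:
        raise ValueError("need at least one participant")
    cfg = covariate_config or STUDY_COVARIATE_CONFIG
    for c in (0, 1):
        if c not in cfg:
            raise ValueError(f"covariate config missing cohort {c}")
        t = cfg[c].get("tests")
        if t is None or len(t) != 3 or abs(sum(t) - 1) > 1e-6:
            raise ValueError("tests marginal must be 3 probabilities summing to 1")

    cohort = np.repeat([0, 1], cohort_counts)
    age = np.empty(n)
    married = np.empty(n, dtype=int)
    educ = np.empty(n, dtype=int)
    tests = np.empty(n, dtype=int)
    for c in (0, 1):
        m = cohort == c
        k = int(m.sum())
        a = rng.normal(cfg[c]["age_mean"], cfg[c]["age_sd"], size=k)
        age[m] = np.clip(a, 18, 49)
        married[m] = rng.random(k) < cfg[c]["married"]
        educ[m] = rng.random(k) < cfg[c]["secondary_education"]
        tests[m] = rng.choice(3, size=k, p=np.asarray(cfg[c]["tests"]))
    df = pd.DataFrame(
        {
            "participant": np.arange(1, n + 1),
            "cohort": cohort,
            "age": np.round(age, 1),
            "secondary_education": educ,
            "married": married,
            "hiv_tests": pd.Categorical.from_codes(
                tests, ["never", "once", "more_than_once"]
            ),
            "tested_once": (tests == 1).astype(int),
            "tested_more_than_once": (tests == 2).astype(int),
            "block": np.arange(n) % n_blocks,
        }
    )
    return df


def assign_classes(
    participants: pd.DataFrame, gamma: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw 0-based class labels from the membership multinomial logit
    (intercept + cohort; reference class last, coefficients zero)."""
    gamma = np.atleast_2d(np.asarray(gamma, dtype=float))
    W = np.column_stack(
        [np.ones(len(participants)), participants["cohort"].to_numpy(dtype=float)]
    )
    logits = np.concatenate([W @ gamma.T, np.zeros((len(W), 1))], axis=1)
    logits -= logits.max(axis=1, keepdims=True)
    p = np.exp(logits)
    p /= p.sum(axis=1, keepdims=True)
    u = rng.random(len(W))[:, None]
    return (p.cumsum(axis=1) < u).sum(axis=1)


def simulate_ranking(
    utilities: np.ndarray, rng: np.random.Generator
) -> tuple[int, int]:
    """Draw (first, second) 0-based choices: a logit draw over all
    alternatives, then a fresh logit draw over the remaining ones with the
    same utilities."""
    u = np.asarray(utilities, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("utilities must be finite")
    f, s = _simulate_rankings(u[None, None, :], rng)
    return int(f[0, 0]), int(s[0, 0])


def _simulate_rankings(U: np.ndarray, rng: np.random.Generator):
    """Vectorized sequential logit draws for utility array U (..., M)."""
    e = np.exp(U - U.max(axis=-1, keepdims=True))
    p1 = e / e.sum(axis=-1, keepdims=True)
    first = (p1.cumsum(axis=-1) < rng.random(U.shape[:-1])[..., None]).sum(axis=-1)
    e2 = e.copy()
    np.put_along_axis(e2, first[..., None], 0.0, axis=-1)
    p2 = e2 / e2.sum(axis=-1, keepdims=True)
    second = (p2.cumsum(axis=-1) < rng.random(U.shape[:-1])[..., None]).sum(axis=-1)
    return first, second


@dataclass
class GroundTruth:
    """What the generator knew: per-participant true class (0-based), true
    random-effect scores (n, D), and the generating parameters."""

    classes: np.ndarray
    F: np.ndarray
    params: RELCLParams

    def to_dict(self) -> dict:
        return {
            "classes": self.classes.tolist(),
            "F": self.F.tolist(),
            "params": self.params.to_dict(),
        }


def simulate_dataset(
    scheme: AttributeScheme,
    design: ChoiceDesign,
    params: RELCLParams,
    n: int | None = None,
    rng: np.random.Generator | None = None,
    participants: pd.DataFrame | None = None,
    covariate_config: dict | None = None,
    cohort_counts: tuple[int, int] | None = None,
) -> tuple[RankingDataset, GroundTruth]:
    """Simulate a full ranked-choice dataset.

    Each participant receives one design block (task order and alternative
    order randomized per participant), a latent class drawn from the
    membership logit, and i.i.d. standard-normal domain scores F; rankings
    follow the exploded logit at the class/individual utilities.
    """
    if rng is None:
        rng = np.random.default_rng()
    if participants is None:
        participants = draw_participants(
            n, covariate_config, rng, cohort_counts, n_blocks=design.n_blocks
        )
    participants = participants.reset_index(drop=True)
    n = len(participants)
    T = design.tasks_per_block
    M = design.n_alternatives_per_task
    if np.any(participants["block"].to_numpy() >= design.n_blocks):
        raise ValueError("participant block exceeds design blocks")

    classes = assign_classes(participants, params.gamma, rng) \
        if params.n_classes > 1 else np.zeros(n, dtype=int)
    F = rng.standard_normal((n, params.n_effects))

    levels = np.empty((n, T, M, scheme.n_attributes), dtype=int)
    for i in range(n):
        levels[i] = randomize_for_participant(
            design, int(participants.loc[i, "block"]), rng
        )
    Z = code_levels(scheme, levels)  # (n, T, M, P)
    b = params.beta[classes] + F @ params.lam  # (n, P)
    U = np.einsum("ntmp,np->ntm", Z, b)
    first, second = _simulate_rankings(U, rng)

    dataset = RankingDataset(scheme, levels, first, second, participants, Z)
    return dataset, GroundTruth(classes=classes, F=F, params=params)
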
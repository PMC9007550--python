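"""Numerical integration over the standard-normal random effects.

Default is tensor-product Gauss–Hermite quadrature (probabilists' weight),
which is deterministic and accurate for the smooth integrands arising here.
A Halton-sequence simulated-likelihood grid is available as an alternative
for higher-dimensional experimentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy.stats import norm, qmc

__all__ = ["QuadratureGrid", "gauss_hermite_grid", "halton_grid"]


@dataclass(frozen=True)
class QuadratureGrid:
    """Nodes (Q, D) and normalized weights (Q,) approximating E_{F~N(0,I_D)}.

    With D = 0 the grid degenerates to a single empty node of weight 1, so the
    same code path handles models without random effects.
    """

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        if self.nodes.ndim != 2 or len(self.weights) != len(self.nodes):
            raise ValueError("nodes must be (Q, D) with matching weights")
        if np.any(self.weights <= 0):
            raise ValueError("weights must be positive")
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("weights must be normalized")

    @property
    def n_nodes(self) -> int:
        return len(self.weights)

    @property
    def n_dim(self) -> int:
        return self.nodes.shape[1]


def gauss_hermite_grid(n_dim: int, n_nodes: int = 7) -> QuadratureGrid:
    """Tensor product of 1-D probabilists' Gauss–Hermite rules."""
    if n_dim == 0:
        return QuadratureGrid(np.zeros((1, 0)), np.ones(1))
    x, w = hermegauss(n_nodes)
    w = w / w.sum()
    grids = np.meshgrid(*([x] * n_dim), indexing="ij")
    nodes = np.stack([g.reshape(-1) for g in grids], axis=1)
    weights = np.ones(n_nodes**n_dim)
    for d in range(n_dim):
        weights *= w[np.meshgrid(*([np.arange(n_nodes)] * n_dim), indexing="ij")[d].reshape(-1)]
    return QuadratureGrid(nodes, weights / weights.sum())


def halton_grid(n_dim: int, n_draws: int = 200, seed: int = 0) -> QuadratureGrid:
    """Equal-weight grid of standard-normal quantiles of a scrambled Halton
    sequence (simulated maximum likelihood)."""
    if n_dim == 0:
        return QuadratureGrid(np.zeros((1, 0)), np.ones(1))
    sampler = qmc.Halton(d=n_dim, scramble=True, seed=seed)
    u = sampler.random(n_draws)
    nodes = norm.ppf(u)
    return QuadratureGrid(nodes, np.full(n_draws, 1.0 / n_draws))
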
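"""Parameter container for the random effects latent class logit model.

The model has X latent preference classes and D class-independent random
effects.  Per class x, the utility of an alternative with effects-coded row z
is  z·β_x + Σ_d F_d (z·λ_d),  where F ~ N(0, I_D) at the individual level and
λ_d is nonzero only on the contrasts of attributes assigned to domain d.
Class membership follows a multinomial logit on participant covariates with
the last class as reference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .scheme import AttributeScheme, contract_levels, expand_contrasts

__all__ = ["RELCLParams", "n_free_params"]


@dataclass
class RELCLParams:
    """β: (X, P) free contrasts per class; λ: (D, P) loadings with the domain
    mask enforced; γ: (X−1, 1+C) membership coefficients (intercept first),
    identically empty when X == 1."""

    scheme: AttributeScheme
    beta: np.ndarray
    lam: np.ndarray
    gamma: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        self.lam = np.asarray(self.lam, dtype=float).reshape(-1, self.scheme.n_contrasts) \
            if np.size(self.lam) else np.zeros((0, self.scheme.n_contrasts))
        self.gamma = np.asarray(self.gamma, dtype=float).reshape(self.n_classes - 1, -1) \
            if np.size(self.gamma) else np.zeros((self.n_classes - 1, 0))
        P = self.scheme.n_contrasts
        if self.beta.shape[1] != P:
            raise ValueError(f"beta needs {P} columns")
        mask = self.domain_mask
        if np.any(self.lam[~mask] != 0):
            raise ValueError("loadings must be zero outside their domain")

    # ---- shapes ------------------------------------------------------------
    @property
    def n_classes(self) -> int:
        return self.beta.shape[0]

    @property
    def n_effects(self) -> int:
        return self.lam.shape[0]

    @property
    def n_contrasts(self) -> int:
        return self.beta.shape[1]

    @property
    def domain_mask(self) -> np.ndarray:
        return self.scheme.domain_mask(self.n_effects)

    # ---- derived quantities ------------------------------------------------
    def expanded_beta(self) -> np.ndarray:
        """(X, total levels) per-level coefficients; rows sum to zero within
        each attribute."""
        return expand_contrasts(self.scheme, self.beta)

    def expanded_lam(self) -> np.ndarray:
        """(D, total levels) per-level loadings."""
        return expand_contrasts(self.scheme, self.lam)

    def membership_logits(self, W: np.ndarray) -> np.ndarray:
        """(n, X) log membership probabilities given covariate design W
        (n, 1+C) whose first column is the intercept."""
        n = W.shape[0]
        logits = np.zeros((n, self.n_classes))
        if self.n_classes > 1:
            logits[:, :-1] = W @ self.gamma.T
        logits -= logits.max(axis=1, keepdims=True)
        return logits - np.log(np.exp(logits).sum(axis=1, keepdims=True))

    def class_shares(self, W: np.ndarray) -> np.ndarray:
        return np.exp(self.membership_logits(W)).mean(axis=0)

    def copy(self) -> "RELCLParams":
        return RELCLParams(
            self.scheme, self.beta.copy(), self.lam.copy(), self.gamma.copy()
        )

    # ---- flat packing (for optimizers) --------------------------------------
    def pack(self) -> np.ndarray:
        return np.concatenate(
            [self.beta.ravel(), self.lam[self.domain_mask], self.gamma.ravel()]
        )

    def unpack(self, theta: np.ndarray) -> "RELCLParams":
        """New params with the same shapes filled from flat vector theta."""
        X, P, D = self.n_classes, self.n_contrasts, self.n_effects
        mask = self.domain_mask
        nb, nl = X * P, int(mask.sum())
        beta = theta[:nb].reshape(X, P)
        lam = np.zeros((D, P))
        lam[mask] = theta[nb : nb + nl]
        gamma = theta[nb + nl :].reshape(self.gamma.shape)
        return RELCLParams(self.scheme, beta, lam, gamma)

    @property
    def n_free(self) -> int:
        return self.beta.size + int(self.domain_mask.sum()) + self.gamma.size

    # ---- serialization -------------------------------------------------------
    def to_dict(self) -> dict:
        labels = [f"{a}:{lv}" for a, lv in self.scheme.level_labels()]
        return {
            "n_classes": self.n_classes,
            "n_effects": self.n_effects,
            "level_labels": labels,
            "beta_expanded": self.expanded_beta().tolist(),
            "lambda_expanded": self.expanded_lam().tolist(),
            "gamma": self.gamma.tolist(),
            "scheme": self.scheme.to_dict(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict, scheme: AttributeScheme | None = None) -> "RELCLParams":
        if scheme is None:
            scheme = AttributeScheme.from_dict(d["scheme"])
        beta = contract_levels(scheme, np.asarray(d["beta_expanded"], dtype=float))
        lam_exp = np.asarray(d["lambda_expanded"], dtype=float)
        D = lam_exp.shape[0] if lam_exp.size else 0
        lam = contract_levels(scheme, lam_exp) if D else np.zeros((0, scheme.n_contrasts))
        if D:
            lam = np.where(scheme.domain_mask(D), lam, 0.0)
        gamma = np.asarray(d.get("gamma", []), dtype=float)
        return cls(scheme, np.atleast_2d(beta), lam, gamma)

    @classmethod
    def from_json(cls, path, scheme: AttributeScheme | None = None) -> "RELCLParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh), scheme)

    @classmethod
    def from_expanded(
        cls,
        scheme: AttributeScheme,
        beta_expanded: np.ndarray,
        lam_expanded: np.ndarray | None = None,
        gamma: np.ndarray | None = None,
    ) -> "RELCLParams":
        """Build from per-level coefficient tables (e.g. a published report);
        each attribute block is re-centered before contraction, so rounded
        tables are accepted."""
        beta = np.atleast_2d(contract_levels(scheme, np.atleast_2d(beta_expanded)))
        X = beta.shape[0]
        if lam_expanded is None or np.size(lam_expanded) == 0:
            lam = np.zeros((0, scheme.n_contrasts))
        else:
            lam_exp = np.atleast_2d(lam_expanded)
            lam = contract_levels(scheme, lam_exp)
            lam = np.where(scheme.domain_mask(lam_exp.shape[0]), lam, 0.0)
        if gamma is None:
            gamma = np.zeros((X - 1, 1))
        return cls(scheme, beta, lam, np.asarray(gamma, dtype=float))


def n_free_params(
    scheme: AttributeScheme,
    n_classes: int,
    n_effects: int,
    membership_covariates: int = 0,
) -> int:
    """Number of free parameters: X·Σ(L_a−1) free utility contrasts, the free
    loadings of the first D domains, and (X−1)·(1+C) membership coefficients."""
    P = scheme.n_contrasts
    n_load = int(scheme.domain_mask(n_effects).sum()) if n_effects else 0
    memb = (n_classes - 1) * (1 + membership_covariates)
    return n_classes * P + n_load + memb
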
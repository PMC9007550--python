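"""Attribute schemes and effects coding for discrete choice experiments.

An :class:`AttributeScheme` lists the attributes of the hypothetical
alternatives shown in a DCE, the labels of each attribute's levels, and the
assignment of each attribute to a preference *domain* (the grouping used by
the factor-structured random effects).  Attributes whose levels cannot be
combined freely (e.g. a counseling format that forces a particular partner
notification mode) are merged into a single *compound* attribute whose levels
are exactly the feasible combinations.

All level indices are 1-based externally, matching survey-style coding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "Attribute",
    "AttributeScheme",
    "build_compound_attribute",
    "effects_code",
    "expand_contrasts",
    "coded_row",
    "hiv_testing_scheme",
]


@dataclass(frozen=True)
class Attribute:
    """One attribute: a name, ordered level labels, a domain index (1-based),
    and whether the levels are ordered (monotone preference expected)."""

    name: str
    levels: tuple[str, ...]
    domain: int
    ordered: bool = False

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise ValueError(f"attribute {self.name!r} needs >= 2 levels")
        if self.domain < 1:
            raise ValueError("domain indices are 1-based")

    @property
    def n_levels(self) -> int:
        return len(self.levels)


@dataclass(frozen=True)
class AttributeScheme:
    """Ordered collection of attributes with domain assignments.

    ``feasibility_rules`` records the forbidden (attribute-level) combinations
    that were folded into compound attributes; they are kept for provenance
    and for validating imported designs.
    """

    attributes: tuple[Attribute, ...]
    feasibility_rules: tuple[tuple[tuple[str, str], ...], ...] = field(
        default_factory=tuple
    )

    def __post_init__(self) -> None:
        names = [a.name for a in self.attributes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate attribute names")

    @property
    def n_attributes(self) -> int:
        return len(self.attributes)

    @property
    def n_levels_total(self) -> int:
        """Total number of levels across attributes = number of expanded
        (per-level) coefficient rows in a report table."""
        return sum(a.n_levels for a in self.attributes)

    @property
    def n_contrasts(self) -> int:
        """Number of free effects-coded contrasts, sum of (L_a - 1)."""
        return sum(a.n_levels - 1 for a in self.attributes)

    @property
    def n_domains(self) -> int:
        return max(a.domain for a in self.attributes)

    def contrast_slices(self) -> list[slice]:
        """Column slice of each attribute within a coded contrast row."""
        out, start = [], 0
        for a in self.attributes:
            out.append(slice(start, start + a.n_levels - 1))
            start += a.n_levels - 1
        return out

    def level_slices(self) -> list[slice]:
        """Row slice of each attribute within an expanded coefficient vector."""
        out, start = [], 0
        for a in self.attributes:
            out.append(slice(start, start + a.n_levels))
            start += a.n_levels
        return out

    def domain_mask(self, n_domains: int | None = None) -> np.ndarray:
        """Boolean (D, n_contrasts): mask[d-1, j] is True when contrast j
        belongs to an attribute assigned to domain d."""
        if n_domains is None:
            n_domains = self.n_domains
        mask = np.zeros((n_domains, self.n_contrasts), dtype=bool)
        for a, sl in zip(self.attributes, self.contrast_slices()):
            if a.domain <= n_domains:
                mask[a.domain - 1, sl] = True
        return mask

    def level_labels(self) -> list[tuple[str, str]]:
        return [(a.name, lv) for a in self.attributes for lv in a.levels]

    # ---- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "attributes": [
                {
                    "name": a.name,
                    "levels": list(a.levels),
                    "domain": a.domain,
                    "ordered": a.ordered,
                }
                for a in self.attributes
            ],
            "feasibility_rules": [
                [list(pair) for pair in rule] for rule in self.feasibility_rules
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AttributeScheme":
        attrs = tuple(
            Attribute(
                name=a["name"],
                levels=tuple(a["levels"]),
                domain=int(a["domain"]),
                ordered=bool(a.get("ordered", False)),
            )
            for a in d["attributes"]
        )
        rules = tuple(
            tuple(tuple(pair) for pair in rule)
            for rule in d.get("feasibility_rules", [])
        )
        return cls(attributes=attrs, feasibility_rules=rules)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "AttributeScheme":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def build_compound_attribute(
    first_levels: Sequence[str],
    second_levels: Sequence[str],
    forbidden: Sequence[tuple[str, str]],
    sep: str = "; ",
) -> list[str]:
    """Combine two attributes into one whose levels are the feasible pairs.

    Parameters
    ----------
    first_levels, second_levels
        Level labels of the two source attributes.
    forbidden
        Pairs ``(first_label, second_label)`` that cannot co-occur.

    Returns
    -------
    list of str
        Labels ``f"{a}{sep}{b}"`` for each feasible pair, in row-major order.

    Raises
    ------
    ValueError
        If the rules forbid every combination (inconsistent configuration).
    """
    bad = {tuple(p) for p in forbidden}
    unknown = [
        p for p in bad if p[0] not in first_levels or p[1] not in second_levels
    ]
    if unknown:
        raise ValueError(f"rules reference unknown levels: {unknown}")
    levels = [
        f"{a}{sep}{b}"
        for a in first_levels
        for b in second_levels
        if (a, b) not in bad
    ]
    if not levels:
        raise ValueError("feasibility rules forbid every combination")
    return levels


def effects_code(level_index: int, n_levels: int) -> np.ndarray:
    """Effects-coded contrast vector of length ``n_levels - 1``.

    Levels ``1..L-1`` map to unit indicator vectors; the reference level ``L``
    maps to the all-minus-one vector, so any coefficient vector expands to
    per-level values that sum to zero.
    """
    if n_levels < 2:
        raise ValueError("need at least 2 levels")
    if not 1 <= level_index <= n_levels:
        raise ValueError(f"level {level_index} out of range 1..{n_levels}")
    v = np.zeros(n_levels - 1)
    if level_index < n_levels:
        v[level_index - 1] = 1.0
    else:
        v[:] = -1.0
    return v


def coded_row(scheme: AttributeScheme, level_indices: Sequence[int]) -> np.ndarray:
    """Concatenated effects codes of one alternative (one level per attribute)."""
    if len(level_indices) != scheme.n_attributes:
        raise ValueError("one level index per attribute required")
    return np.concatenate(
        [
            effects_code(int(ix), a.n_levels)
            for ix, a in zip(level_indices, scheme.attributes)
        ]
    )


def expand_contrasts(scheme: AttributeScheme, free: np.ndarray) -> np.ndarray:
    """Expand free contrasts to per-level coefficients (last level = −sum).

    Accepts a vector of length ``n_contrasts`` or a stack of such vectors;
    the expanded values sum to zero within each attribute.
    """
    free = np.asarray(free, dtype=float)
    squeeze = free.ndim == 1
    free2 = np.atleast_2d(free)
    if free2.shape[-1] != scheme.n_contrasts:
        raise ValueError(
            f"expected {scheme.n_contrasts} contrasts, got {free2.shape[-1]}"
        )
    parts = []
    for sl in scheme.contrast_slices():
        block = free2[:, sl]
        parts.append(np.concatenate([block, -block.sum(axis=1, keepdims=True)], axis=1))
    out = np.concatenate(parts, axis=1)
    return out[0] if squeeze else out


def contract_levels(scheme: AttributeScheme, expanded: np.ndarray) -> np.ndarray:
    """Inverse of :func:`expand_contrasts`: keep the first ``L−1`` per-level
    values of each attribute (centering each attribute block first, so that
    rounded published tables survive the round trip)."""
    expanded = np.asarray(expanded, dtype=float)
    squeeze = expanded.ndim == 1
    exp2 = np.atleast_2d(expanded)
    if exp2.shape[-1] != scheme.n_levels_total:
        raise ValueError(
            f"expected {scheme.n_levels_total} levels, got {exp2.shape[-1]}"
        )
    parts = []
    for sl in scheme.level_slices():
        block = exp2[:, sl]
        block = block - block.mean(axis=1, keepdims=True)
        parts.append(block[:, :-1])
    out = np.concatenate(parts, axis=1)
    return out[0] if squeeze else out


# --------------------------------------------------------------------------
# The HIV-testing DCE scheme: six policy-relevant attributes, with pre-test
# counseling and partner notification merged into a 5-level compound
# attribute because e.g. couples counseling implies automatic disclosure.
# Domains: 1 = privacy & confidentiality (venue, counseling/notification),
# 2 = invasiveness & perceived accuracy (sample type),
# 3 = accessibility & value (availability, additional services).

COUNSELING_LEVELS = ("One-on-one counseling", "Group counseling", "Couples counseling")
NOTIFICATION_LEVELS = ("self-disclosure", "provider notification", "automatic disclosure")
FORBIDDEN_PAIRS = (
    ("One-on-one counseling", "automatic disclosure"),
    ("Group counseling", "automatic disclosure"),
    ("Couples counseling", "self-disclosure"),
    ("Couples counseling", "provider notification"),
)


def hiv_testing_scheme() -> AttributeScheme:
    """The HIV-testing choice-experiment scheme (16 levels, 11 contrasts)."""
    compound = build_compound_attribute(
        COUNSELING_LEVELS, NOTIFICATION_LEVELS, FORBIDDEN_PAIRS
    )
    return AttributeScheme(
        attributes=(
            Attribute(
                "venue",
                ("Home", "Health facility", "VCT center"),
                domain=1,
            ),
            Attribute(
                "availability",
                ("Weekdays only", "Every day"),
                domain=3,
                ordered=True,
            ),
            Attribute(
                "sample_type",
                ("Arm (venipuncture)", "Finger (finger prick)", "Mouth (oral swab)"),
                domain=2,
            ),
            Attribute(
                "services",
                ("HIV test only", "Health check", "STI examination"),
                domain=3,
            ),
            Attribute("counseling_notification", tuple(compound), domain=1),
        ),
        feasibility_rules=(tuple(FORBIDDEN_PAIRS),),
    )
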
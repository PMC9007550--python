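"""Ranked choice data: container, validation, and the long-CSV dialect.

The interchange format is a single long-format CSV (UTF-8, header, comma
separated): one row per participant × task × alternative with columns
``participant, block, task, alternative, <one column per attribute>,
chosen_first, chosen_second``.  Participant covariates travel in a companion
CSV keyed by ``participant``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scheme import AttributeScheme, effects_code

__all__ = [
    "RankingDataset",
    "read_choice_data",
    "write_choice_data",
    "code_levels",
    "ValidationError",
]


def code_levels(scheme: AttributeScheme, levels: np.ndarray) -> np.ndarray:
    """Effects-code an array (..., n_attributes) of 1-based level indices to
    (..., n_contrasts)."""
    codes = [
        np.array([effects_code(l, a.n_levels) for l in range(1, a.n_levels + 1)])
        for a in scheme.attributes
    ]
    parts = [codes[j][levels[..., j] - 1] for j in range(scheme.n_attributes)]
    return np.concatenate(parts, axis=-1)

MEMBERSHIP_COVARIATE = "cohort"
#: covariates used in the downstream (three-step) analyses, in report order
ANALYSIS_COVARIATES = [
    "age",
    "secondary_education",
    "married",
    "tested_once",
    "tested_more_than_once",
    "cohort",
]


class ValidationError(ValueError):
    """Structural problem in imported choice data; message lists offenders."""


@dataclass
class RankingDataset:
    """Sequential best / second-best responses to blocked choice tasks.

    ``levels``: (n, T, M, A) 1-based attribute-level indices of the
    alternatives as presented; ``first``/``second``: (n, T) 0-based indices of
    the best and second-best alternative; ``participants``: one row per
    participant with covariates and block assignment.
    """

    scheme: AttributeScheme
    levels: np.ndarray
    first: np.ndarray
    second: np.ndarray
    participants: pd.DataFrame
    _coded: np.ndarray | None = field(default=None, repr=False, compare=False)
    _ecache: dict | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        n, T, M, A = self.levels.shape
        if A != self.scheme.n_attributes:
            raise ValueError("level array does not match scheme")
        if self.first.shape != (n, T) or self.second.shape != (n, T):
            raise ValueError("choice arrays must be (n, T)")
        if np.any(self.first == self.second):
            raise ValueError("first and second choice must differ")
        if len(self.participants) != n:
            raise ValueError("participant table does not match data")

    # ---- shapes -------------------------------------------------------------
    @property
    def n_participants(self) -> int:
        return self.levels.shape[0]

    @property
    def n_tasks(self) -> int:
        return self.levels.shape[1]

    @property
    def n_alternatives(self) -> int:
        return self.levels.shape[2]

    @property
    def n_rankings(self) -> int:
        return self.n_participants * self.n_tasks

    @property
    def n_choice_records(self) -> int:
        """Exploded count: each ranking contributes a first and a second
        choice."""
        return 2 * self.n_rankings

    # ---- derived arrays -----------------------------------------------------
    def coded(self) -> np.ndarray:
        """Effects-coded design tensor (n, T, M, P); cached."""
        if self._coded is None:
            self._coded = code_levels(self.scheme, self.levels)
        return self._coded

    def exploded_cache(self) -> dict:
        """Precomputed gather matrices for the batched exploded-logit
        likelihood (see :mod:`relclogit.likelihood`); cached."""
        from .likelihood import build_exploded_cache

        if self._ecache is None:
            self._ecache = build_exploded_cache(
                self.coded(), self.first, self.second
            )
        return self._ecache

    def membership_design(self) -> np.ndarray:
        """(n, 2) design for the class-membership logit: intercept + cohort."""
        return np.column_stack(
            [
                np.ones(self.n_participants),
                self.participants[MEMBERSHIP_COVARIATE].to_numpy(dtype=float),
            ]
        )

    def covariate_matrix(self, columns: list[str] | None = None) -> np.ndarray:
        """(n, C) covariates for the downstream regressions (no intercept)."""
        cols = columns or [
            c for c in ANALYSIS_COVARIATES if c in self.participants.columns
        ]
        return self.participants[cols].to_numpy(dtype=float)

    def subset(self, idx: np.ndarray) -> "RankingDataset":
        return RankingDataset(
            self.scheme,
            self.levels[idx],
            self.first[idx],
            self.second[idx],
            self.participants.iloc[np.atleast_1d(idx)].reset_index(drop=True),
        )

    # ---- long-format CSV ------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        n, T, M, _ = self.levels.shape
        pid = self.participants["participant"].to_numpy()
        block = self.participants["block"].to_numpy()
        rows = {
            "participant": np.repeat(pid, T * M),
            "block": np.repeat(block, T * M),
            "task": np.repeat(np.tile(np.arange(1, T + 1), n), M),
            "alternative": np.tile(np.arange(1, M + 1), n * T),
        }
        for j, a in enumerate(self.scheme.attributes):
            rows[a.name] = self.levels[..., j].reshape(-1)
        alt0 = np.tile(np.arange(M), n * T)
        rows["chosen_first"] = (alt0 == np.repeat(self.first.reshape(-1), M)).astype(int)
        rows["chosen_second"] = (alt0 == np.repeat(self.second.reshape(-1), M)).astype(int)
        return pd.DataFrame(rows)

    def write_csv(self, choices_path, participants_path=None) -> None:
        self.to_frame().to_csv(choices_path, index=False)
        if participants_path is not None:
            self.participants.to_csv(participants_path, index=False)


def write_choice_data(dataset: RankingDataset, choices_path, participants_path=None):
    dataset.write_csv(choices_path, participants_path)


def read_choice_data(
    choices_path,
    scheme: AttributeScheme,
    participants_path=None,
) -> RankingDataset:
    """Read and validate the long-format choice CSV.

    Raises :class:`ValidationError` naming offending rows/tasks when the file
    has missing columns, duplicate (participant, task, alternative) rows, a
    task without exactly one first and one distinct second choice, or an
    alternative count other than the modal one.
    """
    df = pd.read_csv(choices_path)
    attr_names = [a.name for a in scheme.attributes]
    required = ["participant", "block", "task", "alternative", *attr_names,
                "chosen_first", "chosen_second"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"missing columns: {missing}")

    dup = df.duplicated(subset=["participant", "task", "alternative"])
    if dup.any():
        raise ValidationError(
            f"duplicate (participant, task, alternative) rows at lines "
            f"{(df.index[dup] + 2).tolist()[:10]}"
        )
    for j, a in enumerate(scheme.attributes):
        bad = ~df[a.name].between(1, a.n_levels)
        if bad.any():
            raise ValidationError(
                f"attribute {a.name!r}: out-of-range levels at lines "
                f"{(df.index[bad] + 2).tolist()[:10]}"
            )

    df = df.sort_values(["participant", "task", "alternative"], kind="stable")
    grp = df.groupby(["participant", "task"])
    sizes = grp.size()
    M = int(sizes.iloc[0])
    bad_size = sizes[sizes != M]
    if len(bad_size):
        raise ValidationError(f"tasks without {M} alternatives: {bad_size.index.tolist()[:10]}")
    flags = grp[["chosen_first", "chosen_second"]].sum()
    bad_flags = flags[(flags["chosen_first"] != 1) | (flags["chosen_second"] != 1)]
    if len(bad_flags):
        raise ValidationError(
            f"tasks without exactly one first and one second choice: "
            f"{bad_flags.index.tolist()[:10]}"
        )
    both = df[(df["chosen_first"] == 1) & (df["chosen_second"] == 1)]
    if len(both):
        raise ValidationError(
            "first and second choice coincide for tasks: "
            f"{list(zip(both['participant'], both['task']))[:10]}"
        )

    pids = df["participant"].unique()
    n = len(pids)
    T = df.groupby("participant")["task"].nunique().iloc[0]
    levels = np.empty((n, T, M, scheme.n_attributes), dtype=int)
    for j, a in enumerate(scheme.attributes):
        levels[..., j] = df[a.name].to_numpy().reshape(n, T, M)
    first = np.argmax(df["chosen_first"].to_numpy().reshape(n, T, M), axis=2)
    second = np.argmax(df["chosen_second"].to_numpy().reshape(n, T, M), axis=2)

    if participants_path is not None:
        participants = pd.read_csv(participants_path)
        participants = (
            participants.set_index("participant").loc[pids].reset_index()
        )
    else:
        participants = (
            df.groupby("participant")["block"].first().loc[pids].reset_index()
        )
        participants["cohort"] = 0
    return RankingDataset(scheme, levels, first, second, participants)
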
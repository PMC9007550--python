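"""Blocked, randomized choice-task designs.

The generator builds a design of ``n_tasks`` choice tasks, each showing
``n_alts`` alternatives, partitioned into equal blocks.  Rather than a
D-efficiency search, it draws level columns by cycling each attribute's
levels and shuffling (yielding near-exact level balance), then repairs any
task containing duplicate alternatives.  Level balance is screened: every
level's frequency must fall within a tolerance of uniform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scheme import AttributeScheme

__all__ = ["ChoiceDesign", "generate_design", "randomize_for_participant"]


@dataclass(frozen=True)
class ChoiceDesign:
    """A blocked choice design.

    ``levels`` has shape (n_tasks, n_alts, n_attributes) with 1-based level
    indices; ``blocks`` maps each task to its (0-based) block.
    """

    levels: np.ndarray
    blocks: np.ndarray
    n_blocks: int

    def __post_init__(self) -> None:
        if self.levels.ndim != 3:
            raise ValueError("levels must be (n_tasks, n_alts, n_attributes)")
        if len(self.blocks) != self.levels.shape[0]:
            raise ValueError("one block id per task required")
        counts = np.bincount(self.blocks, minlength=self.n_blocks)
        if len(set(counts)) != 1:
            raise ValueError("blocks must partition tasks into equal parts")

    @property
    def n_tasks(self) -> int:
        return self.levels.shape[0]

    @property
    def n_alternatives_per_task(self) -> int:
        return self.levels.shape[1]

    @property
    def tasks_per_block(self) -> int:
        return self.n_tasks // self.n_blocks

    def block_tasks(self, block: int) -> np.ndarray:
        """Indices of the tasks in one block."""
        if not 0 <= block < self.n_blocks:
            raise KeyError(f"unknown block {block}")
        return np.flatnonzero(self.blocks == block)

    def to_frame(self, scheme: AttributeScheme) -> pd.DataFrame:
        """Long CSV layout: one row per task × alternative."""
        n_tasks, n_alts, _ = self.levels.shape
        rows = {
            "block": np.repeat(self.blocks, n_alts),
            "task": np.repeat(np.arange(n_tasks), n_alts),
            "alternative": np.tile(np.arange(1, n_alts + 1), n_tasks),
        }
        for j, a in enumerate(scheme.attributes):
            rows[a.name] = self.levels[:, :, j].reshape(-1)
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, scheme: AttributeScheme) -> "ChoiceDesign":
        df = df.sort_values(["task", "alternative"])
        tasks = df["task"].unique()
        n_alts = int(df["alternative"].max())
        levels = np.empty((len(tasks), n_alts, scheme.n_attributes), dtype=int)
        for j, a in enumerate(scheme.attributes):
            levels[:, :, j] = df[a.name].to_numpy().reshape(len(tasks), n_alts)
        blocks = df.groupby("task")["block"].first().to_numpy()
        return cls(levels=levels, blocks=blocks, n_blocks=int(blocks.max()) + 1)


def _balance_ok(levels: np.ndarray, scheme: AttributeScheme, tol: float) -> bool:
    """Every level frequency within ``tol`` (relative) of uniform."""
    n = levels.shape[0] * levels.shape[1]
    for j, a in enumerate(scheme.attributes):
        counts = np.bincount(levels[:, :, j].reshape(-1), minlength=a.n_levels + 1)[1:]
        target = n / a.n_levels
        if np.any(np.abs(counts - target) > tol * target):
            return False
    return True


def generate_design(
    scheme: AttributeScheme,
    n_tasks: int = 120,
    n_blocks: int = 10,
    n_alts: int = 3,
    rng: np.random.Generator | None = None,
    balance_tol: float = 0.2,
    max_tries: int = 200,
) -> ChoiceDesign:
    """Generate a blocked design with near-uniform level balance.

    Each attribute column is filled by cycling its levels across all
    ``n_tasks × n_alts`` slots and shuffling; within-task duplicate
    alternatives are repaired by re-drawing the offending alternatives.
    """
    if rng is None:
        rng = np.random.default_rng()
    if n_tasks % n_blocks:
        raise ValueError("n_tasks must be divisible by n_blocks")
    n_profiles = int(np.prod([a.n_levels for a in scheme.attributes]))
    if n_profiles < n_alts:
        raise ValueError("scheme admits fewer distinct alternatives than n_alts")

    n_slots = n_tasks * n_alts
    for _ in range(max_tries):
        cols = []
        for a in scheme.attributes:
            col = np.resize(np.arange(1, a.n_levels + 1), n_slots)
            rng.shuffle(col)
            cols.append(col)
        levels = np.stack(cols, axis=1).reshape(n_tasks, n_alts, -1)
        # repair within-task duplicates by redrawing the duplicate alternative
        for t in range(n_tasks):
            for _ in range(100):
                _, idx = np.unique(levels[t], axis=0, return_index=True)
                if len(idx) == n_alts:
                    break
                dup = next(
                    m for m in range(n_alts) if m not in idx
                )
                levels[t, dup] = [
                    rng.integers(1, a.n_levels + 1) for a in scheme.attributes
                ]
            else:  # pragma: no cover - tiny schemes only
                break
        if _balance_ok(levels, scheme, balance_tol):
            blocks = np.repeat(np.arange(n_blocks), n_tasks // n_blocks)
            return ChoiceDesign(levels=levels, blocks=blocks, n_blocks=n_blocks)
    raise RuntimeError("could not generate a balanced feasible design")


def randomize_for_participant(
    design: ChoiceDesign, block: int, rng: np.random.Generator
) -> np.ndarray:
    """One participant's presentation of a block.

    Returns levels of shape (tasks_per_block, n_alts, n_attributes) with the
    block's tasks in random order and each task's alternatives permuted.
    Content (the multiset of tasks, and each task's set of alternatives) is
    unchanged.
    """
    idx = design.block_tasks(block)
    idx = rng.permutation(idx)
    out = design.levels[idx].copy()
    for t in range(len(out)):
        out[t] = out[t][rng.permutation(out.shape[1])]
    return out
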
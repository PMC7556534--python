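"""PTSD severity state space and cohort occupancy containers.

The model tracks a closed cohort across five living severity states
(asymptomatic through extreme PTSD) plus an absorbing dead state.
Occupancy counts are fractional persons: this is a deterministic cohort
model, not a microsimulation.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import numpy as np


class SeverityState(str, Enum):
    ASYMPTOMATIC = "asymptomatic"
    MILD = "mild"
    MODERATE = "moderate"
    SEVERE = "severe"
    EXTREME = "extreme"
    DEAD = "dead"

    @property
    def rank(self) -> int:
        """Severity ordering: 0 = asymptomatic ... 4 = extreme, 5 = dead."""
        return _RANK[self]


_RANK = {s: i for i, s in enumerate(SeverityState)}

#: Living states in increasing severity order; the canonical axis for
#: every occupancy / parameter vector in the package.
LIVING_STATES: tuple[SeverityState, ...] = (
    SeverityState.ASYMPTOMATIC,
    SeverityState.MILD,
    SeverityState.MODERATE,
    SeverityState.SEVERE,
    SeverityState.EXTREME,
)

SYMPTOMATIC_STATES: tuple[SeverityState, ...] = LIVING_STATES[1:]


@dataclass(frozen=True)
class CohortDistribution:
    """Counts of living persons per severity state.

    ``counts`` follows the :data:`LIVING_STATES` order. Counts may be
    fractional (after the first cycle the survivors of a deterministic
    cohort are non-integer).
    """

    counts: np.ndarray = field()

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=float)
        if arr.shape != (len(LIVING_STATES),):
            raise ValueError(
                f"expected {len(LIVING_STATES)} state counts, got shape {arr.shape}"
            )
        if np.any(arr < 0):
            raise ValueError("state counts must be non-negative")
        object.__setattr__(self, "counts", arr)

    @classmethod
    def from_mapping(cls, counts: Mapping[SeverityState | str, float]) -> "CohortDistribution":
        vec = np.zeros(len(LIVING_STATES))
        for key, value in counts.items():
            state = SeverityState(key)
            if state is SeverityState.DEAD:
                raise ValueError("the dead state does not belong in a cohort distribution")
            vec[state.rank] = value
        return cls(vec)

    def as_dict(self) -> dict[SeverityState, float]:
        return {s: float(self.counts[s.rank]) for s in LIVING_STATES}

    def __getitem__(self, state: SeverityState | str) -> float:
        return float(self.counts[SeverityState(state).rank])

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def proportions(self) -> np.ndarray:
        if self.total == 0:
            raise ValueError("empty cohort has no proportions")
        return self.counts / self.total

    def __eq__(self, other: object) -> bool:  # noqa: D105
        if not isinstance(other, CohortDistribution):
            return NotImplemented
        return bool(np.array_equal(self.counts, other.counts))


def largest_remainder_round(weights: Iterable[float], total: int) -> np.ndarray:
    """Allocate ``total`` integer units proportionally to ``weights``.

    Floors the exact shares and hands the remaining units to the cells
    with the largest fractional parts (ties broken by position).
    """
    w = np.asarray(list(weights), dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with a positive sum")
    exact = w / w.sum() * total
    floors = np.floor(exact).astype(int)
    remainder = total - int(floors.sum())
    order = np.argsort(-(exact - floors), kind="stable")
    floors[order[:remainder]] += 1
    return floors
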
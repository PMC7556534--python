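"""Age-specific background annual death probabilities.

The model multiplies a background schedule q(age) by severity-specific
relative risks. The bundled schedule is a synthetic Gompertz table
calibrated to the published anchor q(40) = 0.00139 (see
``data/us_lifetable_2007_synthetic.csv``); any two-column CSV
(age, qx) can be swapped in because the schedule behind the published
anchor is otherwise unstated.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class LifeTable:
    """Ordered (age, annual death probability) pairs, contiguous ages."""

    ages: np.ndarray
    qx: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        qx = np.asarray(self.qx, dtype=float)
        if ages.ndim != 1 or ages.shape != qx.shape or ages.size == 0:
            raise ValueError("life table needs matching, non-empty age and qx columns")
        if not np.array_equal(np.diff(ages), np.ones(ages.size - 1, dtype=int)):
            raise ValueError("life-table ages must be contiguous integers")
        if np.any(qx <= 0) or np.any(qx >= 1):
            raise ValueError("all death probabilities must lie strictly in (0, 1)")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "qx", qx)

    def __eq__(self, other: object) -> bool:  # noqa: D105
        if not isinstance(other, LifeTable):
            return NotImplemented
        return bool(
            np.array_equal(self.ages, other.ages) and np.array_equal(self.qx, other.qx)
        )

    @property
    def min_age(self) -> int:
        return int(self.ages[0])

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])


def mortality_at(table: LifeTable, age: float) -> float:
    """Annual death probability at ``age``.

    Non-integer ages floor to the tabulated year; ages above the table
    maximum clamp to the last entry (conservative, deterministic); ages
    below the table minimum are an error.
    """
    if age < 0:
        raise ValueError("age must be non-negative")
    a = int(np.floor(age))
    if a < table.min_age:
        raise ValueError(f"age {age} below life-table minimum {table.min_age}")
    a = min(a, table.max_age)
    return float(table.qx[a - table.min_age])


def synthetic_gompertz_table(
    q_ref: float = 0.00139,
    ref_age: int = 40,
    slope: float = 0.085,
    max_age: int = 110,
) -> LifeTable:
    """Synthetic exponential-hazard (Gompertz) schedule for tests.

    q(a) = min(0.999, q_ref * exp(slope * (a - ref_age))) on
    [ref_age - 20, max_age]. With the default anchor and a slope of
    0.085/yr (mortality doubling every ~8 years) it tracks the adult
    U.S. female schedule to within ~10%.
    """
    if not 0 < q_ref < 1:
        raise ValueError("q_ref must lie in (0, 1)")
    if slope <= 0:
        raise ValueError("slope must be positive")
    if max_age <= ref_age:
        raise ValueError("max_age must exceed ref_age")
    ages = np.arange(max(0, ref_age - 20), max_age + 1)
    qx = np.minimum(0.999, q_ref * np.exp(slope * (ages - ref_age)))
    return LifeTable(ages=ages, qx=qx)


def read_life_table(path: str | Path) -> LifeTable:
    """Parse and validate a two-column (age, qx) CSV with header."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("life-table CSV needs (age, qx) columns")
    return LifeTable(ages=df.iloc[:, 0].to_numpy(), qx=df.iloc[:, 1].to_numpy())


def write_life_table(table: LifeTable, path: str | Path) -> None:
    pd.DataFrame({"age": table.ages, "qx": table.qx}).to_csv(path, index=False)


def load_bundled_life_table(name: str = "us_lifetable_2007_synthetic.csv") -> LifeTable:
    ref = resources.files("mapcea.data").joinpath(name)
    if not ref.is_file():
        raise FileNotFoundError(name)
    with resources.as_file(ref) as p:
        return read_life_table(p)
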
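"""Annual-cycle Markov cohort simulation.

Each arm of the comparison is a deterministic cohort advanced one year
at a time. Per cycle, each living state loses occupancy to death at
q(age) x RR(state); in the base case survivors remain in their state
(treatment effect is the once-off shift from the intake to the
follow-up distribution), while the relapse scenario moves a fraction of
MAP-arm survivors one severity step per year.

Accounting conventions (see docs/methods.md for rationale):

* end-of-cycle discounting — cycle t flows are divided by (1+r)^t;
* decedents receive half a cycle of utility and medical cost
  (switchable via ``half_cycle_credit``);
* the MAP arm's medical cost phases in the post-treatment cost mix over
  five years: cost(t) = (1-f_t) x [survivor person-years priced at the
  intake mix] + f_t x [priced at actual states]. Mortality and QALYs
  always follow the actual (post-treatment) states;
* the upfront intervention cost is charged undiscounted at t=0;
* deaths are accumulated undiscounted.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .lifetable import mortality_at
from .params import ModelParams
from .states import LIVING_STATES, CohortDistribution

logger = logging.getLogger(__name__)

Arm = Literal["map", "control"]

DEFAULT_PHASE_IN: tuple[float, ...] = (0.0, 0.25, 0.50, 0.75, 1.0)


def phase_in_fraction(t: int, schedule: Sequence[float] = DEFAULT_PHASE_IN) -> float:
    """Fraction of the medical-cost reduction realised in cycle ``t``.

    The default schedule holds costs at their pre-treatment level in the
    first year and releases the reduction in 25% steps, saturating at
    100% from year 5 on.
    """
    if t < 1:
        raise ValueError("cycle index is 1-based")
    return float(schedule[min(t, len(schedule)) - 1])


def discount(value: float, t: int, r: float) -> float:
    """Present value of an end-of-cycle-t flow at annual rate ``r``."""
    if r < 0:
        raise ValueError("discount rate must be non-negative")
    if t < 1:
        raise ValueError("cycle index is 1-based")
    return value / (1.0 + r) ** t


@dataclass(frozen=True)
class Scenario:
    """Relapse scenario: annual one-step severity progression (MAP arm).

    Applied at the end of every cycle ``t >= start_cycle``, so occupancy
    first diverges from the base case in cycle ``start_cycle + 1``.
    Extreme-state patients progress no further.
    """

    p_progression: float
    start_cycle: int = 5

    def __post_init__(self) -> None:
        if not 0 <= self.p_progression <= 1:
            raise ValueError("progression probability must lie in [0, 1]")
        if self.start_cycle < 1:
            raise ValueError("start_cycle is 1-based")


def cycle_step(
    occupancy: CohortDistribution,
    age: float,
    params: ModelParams,
    arm: Arm = "control",
    scenario: Scenario | None = None,
    cycle: int = 1,
) -> tuple[CohortDistribution, np.ndarray]:
    """One annual transition: deaths, then (scenario only) progression.

    Returns the next cycle's occupancy and this cycle's per-state
    deaths. Death probabilities q(age) x RR are clamped at 1 with a
    logged warning if they overflow.
    """
    occ = occupancy.counts
    q = mortality_at(params.life_table, age)
    p_death = q * params.mortality_rrs()
    if np.any(p_death > 1):
        logger.warning("death probability q*RR exceeds 1 at age %s; clamping", age)
        p_death = np.minimum(p_death, 1.0)
    deaths = occ * p_death
    survivors = occ - deaths
    if (
        scenario is not None
        and arm == "map"
        and scenario.p_progression > 0
        and cycle >= scenario.start_cycle
    ):
        moved = survivors[:-1] * scenario.p_progression
        survivors = survivors.copy()
        survivors[:-1] -= moved
        survivors[1:] += moved
    return CohortDistribution(survivors), deaths


@dataclass(frozen=True)
class CycleLedger:
    """Per-cycle accounting row (occupancy is at the start of the cycle)."""

    t: int
    age: float
    occupancy: CohortDistribution
    deaths_by_state: np.ndarray
    deaths: float
    medical_cost: float
    medical_cost_disc: float
    qalys: float
    qalys_disc: float


@dataclass(frozen=True)
class Trajectory:
    """Full ledger for one arm plus cumulative series by horizon."""

    arm: Arm
    start: CohortDistribution
    upfront_cost: float
    cycles: tuple[CycleLedger, ...]
    _cum_cost_disc: np.ndarray = field(repr=False)
    _cum_qalys_disc: np.ndarray = field(repr=False)
    _cum_deaths: np.ndarray = field(repr=False)

    @property
    def horizon(self) -> int:
        return len(self.cycles)

    def _interp(self, series: np.ndarray, horizon: float) -> float:
        """Cumulative value at a possibly fractional horizon (linear
        within the bracketing cycle; horizon 0 = nothing accrued)."""
        if not 0 <= horizon <= self.horizon:
            raise ValueError(f"horizon {horizon} outside simulated range [0, {self.horizon}]")
        full = np.concatenate([[0.0], series])
        lo = int(np.floor(horizon))
        frac = horizon - lo
        if frac == 0:
            return float(full[lo])
        return float(full[lo] + frac * (full[lo + 1] - full[lo]))

    def cumulative_discounted_cost(self, horizon: float) -> float:
        """Discounted medical cost plus the upfront intervention cost."""
        return self.upfront_cost + self._interp(self._cum_cost_disc, horizon)

    def cumulative_discounted_qalys(self, horizon: float) -> float:
        return self._interp(self._cum_qalys_disc, horizon)

    def cumulative_deaths(self, horizon: float) -> float:
        """Cumulative deaths, undiscounted."""
        return self._interp(self._cum_deaths, horizon)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for c in self.cycles:
            row = {
                "arm": self.arm,
                "cycle": c.t,
                "age": c.age,
                "deaths": c.deaths,
                "medical_cost": c.medical_cost,
                "medical_cost_disc": c.medical_cost_disc,
                "qalys": c.qalys,
                "qalys_disc": c.qalys_disc,
            }
            for s in LIVING_STATES:
                row[f"n_{s.value}"] = c.occupancy[s]
            rows.append(row)
        df = pd.DataFrame(rows)
        df["cum_cost_disc"] = self._cum_cost_disc + self.upfront_cost
        df["cum_qalys_disc"] = self._cum_qalys_disc
        df["cum_deaths"] = self._cum_deaths
        return df


def run_cohort(
    params: ModelParams,
    arm: Arm,
    horizon: int | None = None,
    scenario: Scenario | None = None,
    start: CohortDistribution | None = None,
) -> Trajectory:
    """Simulate one arm for ``horizon`` annual cycles.

    The MAP arm starts from the post-treatment (follow-up) distribution
    and carries the upfront intervention cost; the control arm starts
    from the intake distribution at zero upfront cost. The cohort ages
    one year per cycle from ``params.mean_age``; ages beyond the life
    table clamp to its last entry.
    """
    if arm not in ("map", "control"):
        raise ValueError(f"arm must be 'map' or 'control', got {arm!r}")
    horizon = params.horizon if horizon is None else int(horizon)
    if horizon < 1:
        raise ValueError("horizon must be at least one year")
    if start is None:
        start = params.followup_distribution if arm == "map" else params.intake_distribution
    upfront = params.intervention_cost.total * params.cohort_size if arm == "map" else 0.0

    u = params.utilities()
    c = params.annual_costs()
    r = params.discount_rate
    percap_intake = float(params.intake_distribution.proportions @ c)
    half = 0.5 if params.half_cycle_credit else 0.0

    occ_dist = start
    cycles: list[CycleLedger] = []
    cost_disc = np.empty(horizon)
    qalys_disc = np.empty(horizon)
    deaths_tot = np.empty(horizon)
    for t in range(1, horizon + 1):
        age = params.mean_age + t - 1
        occ = occ_dist.counts
        next_dist, deaths = cycle_step(occ_dist, age, params, arm, scenario, cycle=t)
        py = occ - (1.0 - half) * deaths  # person-years lived this cycle
        qalys = float(py @ u)
        cost_actual = float(py @ c)
        if arm == "map":
            f = phase_in_fraction(t, params.cost_phase_in)
            cost = (1.0 - f) * float(py.sum()) * percap_intake + f * cost_actual
        else:
            cost = cost_actual
        cycles.append(
            CycleLedger(
                t=t,
                age=age,
                occupancy=occ_dist,
                deaths_by_state=deaths,
                deaths=float(deaths.sum()),
                medical_cost=cost,
                medical_cost_disc=discount(cost, t, r),
                qalys=qalys,
                qalys_disc=discount(qalys, t, r),
            )
        )
        cost_disc[t - 1] = cycles[-1].medical_cost_disc
        qalys_disc[t - 1] = cycles[-1].qalys_disc
        deaths_tot[t - 1] = cycles[-1].deaths
        occ_dist = next_dist

    return Trajectory(
        arm=arm,
        start=start,
        upfront_cost=upfront,
        cycles=tuple(cycles),
        _cum_cost_disc=np.cumsum(cost_disc),
        _cum_qalys_disc=np.cumsum(qalys_disc),
        _cum_deaths=np.cumsum(deaths_tot),
    )


def trajectories_to_frame(traj_map: Trajectory, traj_control: Trajectory) -> pd.DataFrame:
    """Tidy per-cycle export, one row per cycle per arm."""
    return pd.concat(
        [traj_map.to_dataframe(), traj_control.to_dataframe()], ignore_index=True
    )
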
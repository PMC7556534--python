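"""Cost-effectiveness outcomes: net cost, QALYs gained, ICER, break-even.

Sign convention: net cost = MAP arm minus control; negative net cost is
a saving. "Dominant" flags a strategy that is cheaper and more
effective, in which case no ratio is reported.
"""
from __future__ import annotations

from dataclasses import dataclass

from .engine import Scenario, Trajectory, run_cohort
from .params import ModelParams

#: Dominance / degeneracy flags returned instead of a numeric ICER.
DOMINANT = "dominant"
DOMINATED = "dominated"
INDETERMINATE = "indeterminate"


def icer(net_cost: float, qalys_gained: float) -> float | str:
    """ICER or a dominance flag.

    A ratio is only meaningful when both increments are positive; a
    cheaper, more effective strategy is dominant; a costlier, less
    effective one is dominated; anything else (including zero QALY
    increments) is indeterminate rather than a division.
    """
    if net_cost > 0 and qalys_gained > 0:
        return net_cost / qalys_gained
    if net_cost < 0 and qalys_gained > 0:
        return DOMINANT
    if net_cost > 0 and qalys_gained < 0:
        return DOMINATED
    return INDETERMINATE


@dataclass(frozen=True)
class CEAResult:
    """Paired-arm comparison at one analytic horizon.

    Costs and QALYs are discounted (costs include the upfront
    intervention cost); deaths are undiscounted.
    """

    horizon: float
    cost_map: float
    cost_control: float
    qalys_map: float
    qalys_control: float
    deaths_map: float
    deaths_control: float

    @property
    def net_cost(self) -> float:
        return self.cost_map - self.cost_control

    @property
    def qalys_gained(self) -> float:
        return self.qalys_map - self.qalys_control

    @property
    def deaths_averted(self) -> float:
        return self.deaths_control - self.deaths_map

    @property
    def icer(self) -> float | str:
        return icer(self.net_cost, self.qalys_gained)

    @property
    def dominant(self) -> bool:
        return self.icer == DOMINANT


def compare(traj_map: Trajectory, traj_control: Trajectory, horizon: float) -> CEAResult:
    """Difference the two arms' cumulative ledgers at ``horizon``.

    Fractional horizons interpolate every cumulative quantity linearly
    within the bracketing cycle, consistently across costs, QALYs and
    deaths.
    """
    # tolerate the published intake over-count of one person in 1,000
    if abs(traj_map.start.total - traj_control.start.total) > 2e-3 * traj_map.start.total:
        raise ValueError(
            f"mismatched cohort sizes: {traj_map.start.total} vs {traj_control.start.total}"
        )
    return CEAResult(
        horizon=horizon,
        cost_map=traj_map.cumulative_discounted_cost(horizon),
        cost_control=traj_control.cumulative_discounted_cost(horizon),
        qalys_map=traj_map.cumulative_discounted_qalys(horizon),
        qalys_control=traj_control.cumulative_discounted_qalys(horizon),
        deaths_map=traj_map.cumulative_deaths(horizon),
        deaths_control=traj_control.cumulative_deaths(horizon),
    )


def run_comparison(
    params: ModelParams,
    horizon: int | None = None,
    scenario: Scenario | None = None,
) -> tuple[Trajectory, Trajectory]:
    """Both arms under one parameter set (scenario applies to MAP only)."""
    h = params.horizon if horizon is None else horizon
    traj_map = run_cohort(params, "map", horizon=h, scenario=scenario)
    traj_control = run_cohort(params, "control", horizon=h)
    return traj_map, traj_control


def break_even_horizon(
    params: ModelParams,
    max_horizon: int | None = None,
    scenario: Scenario | None = None,
) -> float | None:
    """Smallest horizon at which cumulative discounted net cost <= 0.

    Linearly interpolated between the bracketing integer horizons
    (sub-annual resolution); ``None`` if the intervention never pays
    itself back within ``max_horizon``.
    """
    max_h = params.horizon if max_horizon is None else max_horizon
    if max_h < 2:
        raise ValueError("need a horizon of at least two years to bracket break-even")
    traj_map, traj_control = run_comparison(params, horizon=max_h, scenario=scenario)

    def net(h: float) -> float:
        return traj_map.cumulative_discounted_cost(h) - traj_control.cumulative_discounted_cost(h)

    prev = net(0.0)
    if prev <= 0:
        return 0.0
    for t in range(1, max_h + 1):
        cur = net(float(t))
        if cur <= 0:
            return (t - 1) + prev / (prev - cur)
        prev = cur
    return None
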
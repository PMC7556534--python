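"""Deterministic sensitivity machinery.

One-way (tornado) and two-way sweeps, bisection threshold search, and
the disease-progression scenario. All of them re-evaluate the full
two-arm model with one or two parameters moved off base; the
``evaluate_output`` helper is the single place that knows how to turn a
dotted parameter path into a rebuilt model, including the two paths
that are not plain inputs:

* ``effectiveness.mean_caps_change`` is routed through the synthetic
  cohort's CAPS -> distribution mapping (the model's effectiveness
  input is a severity distribution, not a score);
* ``progression.rate`` switches on the relapse scenario.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Callable, Mapping

import numpy as np
import pandas as pd
from scipy import optimize

from . import cohort
from .engine import Scenario
from .outcomes import CEAResult, compare, run_comparison
from .params import ModelParams
from .states import LIVING_STATES

#: Seed for the reference synthetic cohort used to map effectiveness
#: draws to severity distributions. Fixed so deterministic sweeps are
#: deterministic; the mapping is insensitive to it (marginals match
#: exactly by construction for every seed).
_CALIBRATION_SEED = 20_19

_records_cache: dict[tuple, pd.DataFrame] = {}


def reference_records(params: ModelParams, seed: int = _CALIBRATION_SEED) -> pd.DataFrame:
    """Calibrated synthetic cohort for this parameter set (cached)."""
    key = (
        seed,
        tuple(params.intake_distribution.counts),
        tuple(params.followup_distribution.counts),
        params.baseline_caps_mean,
        params.baseline_caps_sd,
    )
    if key not in _records_cache:
        spec = cohort.CohortSpec(
            baseline_mean=params.baseline_caps_mean,
            baseline_sd=params.baseline_caps_sd,
            effect=params.effectiveness,
            n=int(params.intake_distribution.total),
        )
        _records_cache[key] = cohort.calibrate_cohort(
            params.intake_distribution, params.followup_distribution, spec, seed=seed
        )
    return _records_cache[key]


def rebuild_params(
    params: ModelParams,
    overrides: Mapping[str, Any],
    records: pd.DataFrame | None = None,
) -> tuple[ModelParams, Scenario | None]:
    """Apply overrides, translating the special paths described above."""
    overrides = dict(overrides)
    scenario = None
    p_prog = overrides.pop("progression.rate", None)
    start_cycle = overrides.pop(
        "progression.start_cycle", params.progression.get("start_cycle", 5)
    )
    if p_prog is not None and p_prog > 0:
        scenario = Scenario(p_progression=float(p_prog), start_cycle=int(start_cycle))

    new_mean = overrides.pop("effectiveness.mean_caps_change", None)
    if new_mean is not None and new_mean != params.effectiveness.mean_caps_change:
        if records is None:
            records = reference_records(params)
        dist = cohort.apply_effect_shift(
            records, new_mean, base_mean_change=params.effectiveness.mean_caps_change
        )
        overrides["followup_distribution"] = dist
    return (params.with_overrides(overrides) if overrides else params), scenario


OutputSpec = str | Callable[[CEAResult], float]


def _extract(result: CEAResult, output: OutputSpec) -> float:
    if callable(output):
        return float(output(result))
    if output in ("net_cost", "qalys_gained", "deaths_averted"):
        return float(getattr(result, output))
    if output == "icer":
        value = result.icer
        if not isinstance(value, float):
            raise ValueError(f"ICER is not numeric here ({value})")
        return value
    raise ValueError(f"unknown output {output!r}")


def evaluate_output(
    params: ModelParams,
    overrides: Mapping[str, Any],
    output: OutputSpec = "net_cost",
    horizon: int | None = None,
    records: pd.DataFrame | None = None,
) -> float:
    """Model output at ``horizon`` with ``overrides`` applied."""
    p, scenario = rebuild_params(params, overrides, records)
    h = p.horizon if horizon is None else horizon
    traj_map, traj_control = run_comparison(p, horizon=h, scenario=scenario)
    return _extract(compare(traj_map, traj_control, h), output)


# ---------------------------------------------------------------------------
# One-way / tornado
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParamRange:
    path: str
    low: float
    base: float
    high: float
    note: str = ""

    def __post_init__(self) -> None:
        if not self.low <= self.base <= self.high:
            raise ValueError(f"{self.path}: need low <= base <= high")


@dataclass(frozen=True)
class TornadoEntry:
    path: str
    low: float
    high: float
    output_at_low: float
    output_at_high: float

    @property
    def span(self) -> float:
        return abs(self.output_at_high - self.output_at_low)


def one_way(
    params: ModelParams,
    ranges: list[ParamRange],
    output: OutputSpec = "net_cost",
    horizon: int | None = None,
) -> list[TornadoEntry]:
    """Vary each parameter to its endpoints, others at base; sort by span."""
    entries = []
    for r in ranges:
        lo = evaluate_output(params, {r.path: r.low}, output, horizon)
        hi = evaluate_output(params, {r.path: r.high}, output, horizon)
        entries.append(
            TornadoEntry(path=r.path, low=r.low, high=r.high, output_at_low=lo, output_at_high=hi)
        )
    return sorted(entries, key=lambda e: -e.span)


def default_tornado_ranges(params: ModelParams) -> list[ParamRange]:
    """The published one-way ranges (plus the cost-multiplier band).

    RR ranges use mean +/- 1.96 SD clipped below at 1; the medical-cost
    multiplier mirrors the +/-30% intervention-cost band because no
    deterministic cost range is printed.
    """
    sens = params.sensitivity
    eff = params.effectiveness
    half_ci = 1.96 * eff.sampling_sd
    rel = float(sens.get("intervention_cost_rel_range", 0.30))
    total = params.intervention_cost.total
    lo_m, hi_m = sens.get("medical_cost_multiplier_range", [0.7, 1.3])
    ranges = [
        ParamRange("medical_cost_multiplier", lo_m, 1.0, hi_m, "multiplier"),
        ParamRange(
            "effectiveness.mean_caps_change",
            eff.mean_caps_change - half_ci,
            eff.mean_caps_change,
            eff.mean_caps_change + half_ci,
            "95% CI of the mean change",
        ),
        ParamRange("intervention_cost.total", total * (1 - rel), total, total * (1 + rel)),
        ParamRange(
            "discount_rate", *_triplet(sens.get("discount_rate_range"), params.discount_rate)
        ),
        ParamRange("mean_age", *_triplet(sens.get("mean_age_range"), params.mean_age)),
    ]
    u_ranges = sens.get("utility_ranges", {})
    for s in LIVING_STATES[1:]:
        u = params.state_params[s].utility
        if s.value in u_ranges:
            lo, hi = u_ranges[s.value]
        else:
            rel_u = float(u_ranges.get(f"{s.value}_rel", 0.10))
            lo, hi = u * (1 - rel_u), min(1.0, u * (1 + rel_u))
        ranges.append(ParamRange(f"state_params.{s.value}.utility", lo, u, hi))
    rr_sds = sens.get("rr_sds", {})
    for s in LIVING_STATES[1:]:
        rr = params.state_params[s].mortality_rr
        sd = float(rr_sds.get(s.value, 0.0))
        ranges.append(
            ParamRange(
                f"state_params.{s.value}.mortality_rr",
                max(1.0, rr - 1.96 * sd),
                rr,
                rr + 1.96 * sd,
                "mean +/- 1.96 SD, clipped at 1",
            )
        )
    return ranges


def _triplet(bounds: Any, base: float) -> tuple[float, float, float]:
    lo, hi = bounds
    return float(lo), float(base), float(hi)


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.path,
                "low": e.low,
                "high": e.high,
                "output_at_low": e.output_at_low,
                "output_at_high": e.output_at_high,
                "span": e.span,
            }
            for e in entries
        ]
    )


# ---------------------------------------------------------------------------
# Two-way grid
# ---------------------------------------------------------------------------

def two_way(
    params: ModelParams,
    path_a: str,
    values_a: np.ndarray,
    path_b: str,
    values_b: np.ndarray,
    output: OutputSpec = "net_cost",
    horizon: int | None = None,
) -> pd.DataFrame:
    """Full-factorial evaluation; long-format (a, b, output) frame.

    ``path_b`` may be the pseudo-path ``"horizon"`` to sweep the
    analytic horizon itself.
    """
    rows = []
    for a in np.atleast_1d(values_a):
        for b in np.atleast_1d(values_b):
            if path_b == "horizon":
                value = evaluate_output(params, {path_a: float(a)}, output, horizon=int(b))
            else:
                value = evaluate_output(
                    params, {path_a: float(a), path_b: float(b)}, output, horizon
                )
            rows.append({path_a: float(a), path_b: float(b), "output": value})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Threshold search
# ---------------------------------------------------------------------------

def cost_threshold(
    params: ModelParams,
    knob: str,
    bracket: tuple[float, float],
    target: float = 0.0,
    output: OutputSpec = "net_cost",
    horizon: int | None = None,
) -> float:
    """Knob value where ``output`` crosses ``target`` (Brent bisection).

    Requires a sign change over the bracket; otherwise raises with the
    endpoint values so the caller can widen it.
    """
    lo, hi = bracket

    def g(x: float) -> float:
        return evaluate_output(params, {knob: x}, output, horizon) - target

    g_lo, g_hi = g(lo), g(hi)
    if np.sign(g_lo) == np.sign(g_hi):
        raise ValueError(
            f"no sign change for {knob} over [{lo}, {hi}]: "
            f"output-target = {g_lo:.6g} and {g_hi:.6g}"
        )
    return float(optimize.brentq(g, lo, hi, rtol=1e-6))


# ---------------------------------------------------------------------------
# Progression scenario
# ---------------------------------------------------------------------------

def progression_scenario(
    params: ModelParams,
    p_prog: float = 0.06,
    start_cycle: int | None = None,
    horizon: int | None = None,
) -> CEAResult:
    """Relapse scenario vs the unchanged control arm.

    MAP-arm survivors move one severity step per year with probability
    ``p_prog`` from ``start_cycle`` on (extreme patients progress no
    further). ``p_prog = 0`` is exactly the base case.
    """
    if not 0 <= p_prog <= 0.2:
        raise ValueError("progression probability must lie in [0, 0.2]")
    sc = params.progression.get("start_cycle", 5) if start_cycle is None else start_cycle
    h = params.horizon if horizon is None else horizon
    scenario = Scenario(p_progression=p_prog, start_cycle=int(sc)) if p_prog > 0 else None
    traj_map, traj_control = run_comparison(params, horizon=h, scenario=scenario)
    return compare(traj_map, traj_control, h)
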
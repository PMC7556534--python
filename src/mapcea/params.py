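"""Model inputs: severity banding, parameter derivation rules, base case.

All base-case values are the published model inputs for a cohort of
1,000 chronic, treatment-resistant PTSD patients (2019 USD throughout):
the intake / post-treatment severity distributions, per-state utilities,
annual medical costs anchored on the severe state, mortality relative
risks anchored on an all-cause PTSD RR of 2.28, the micro-costed
intervention cost, and discounting / horizon settings.

Two derivation rules are exposed as first-class operations because the
published state costs and RRs are generated, not free inputs:

* state annual costs: extreme = 1.2 x severe, moderate = 0.75 x severe,
  mild = 0.5 x severe, asymptomatic passed through;
* mortality RRs: severe = 1.1 x base, extreme = 1.1 x severe,
  moderate = 0.9 x base, mild = 0.85 x moderate, asymptomatic = 1.

Monetary arithmetic is unrounded internally; rounding happens only at
reporting.
"""
from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Any, Mapping, Sequence

import numpy as np
import yaml

from .lifetable import LifeTable, load_bundled_life_table, read_life_table
from .states import (
    LIVING_STATES,
    SYMPTOMATIC_STATES,
    CohortDistribution,
    SeverityState,
)

# ---------------------------------------------------------------------------
# Severity bands (CAPS-IV total score -> state)
# ---------------------------------------------------------------------------

#: (lower bound, upper bound, state); bounds inclusive, integer-score
#: convention. The extreme band is open-ended (CAPS-IV totals can
#: exceed 100).
SeverityBands = tuple[tuple[float, float, SeverityState], ...]

DEFAULT_BANDS: SeverityBands = (
    (0, 19, SeverityState.ASYMPTOMATIC),
    (20, 39, SeverityState.MILD),
    (40, 59, SeverityState.MODERATE),
    (60, 79, SeverityState.SEVERE),
    (80, math.inf, SeverityState.EXTREME),
)


def validate_bands(bands: SeverityBands) -> None:
    """Bands must be contiguous, non-overlapping and cover [0, inf)."""
    if len(bands) != len(LIVING_STATES):
        raise ValueError("expected exactly five severity bands")
    if bands[0][0] != 0 or not math.isinf(bands[-1][1]):
        raise ValueError("bands must cover [0, +inf)")
    for (lo, hi, _), (lo2, _, _) in zip(bands, bands[1:]):
        if hi < lo:
            raise ValueError("band upper bound below lower bound")
        if lo2 != hi + 1:
            raise ValueError("bands must be contiguous under the integer-score convention")


def classify_caps(score: float, bands: SeverityBands = DEFAULT_BANDS) -> SeverityState:
    """Map a CAPS-IV total score to its severity state.

    CAPS-IV totals are integer-valued; non-integer inputs are floored
    before banding so the bands are exhaustive.
    """
    if score < 0:
        raise ValueError(f"CAPS score must be non-negative, got {score}")
    s = math.floor(score)
    for lo, hi, state in bands:
        if lo <= s <= hi:
            return state
    raise ValueError(f"no band contains CAPS score {score}")  # pragma: no cover


# ---------------------------------------------------------------------------
# Per-state parameters and their derivation rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StateParams:
    """Utility, annual medical cost and mortality RR for one state."""

    state: SeverityState
    utility: float
    annual_cost: float
    mortality_rr: float

    def __post_init__(self) -> None:
        if not 0 < self.utility <= 1:
            raise ValueError(f"utility must lie in (0, 1], got {self.utility}")
        if self.annual_cost < 0:
            raise ValueError("annual cost must be non-negative")
        if self.mortality_rr <= 0:
            raise ValueError("mortality RR must be positive")


DEFAULT_COST_MULTIPLIERS: dict[SeverityState, float] = {
    SeverityState.EXTREME: 1.2,
    SeverityState.MODERATE: 0.75,
    SeverityState.MILD: 0.5,
}


def derive_state_costs(
    severe_anchor: float,
    multipliers: Mapping[SeverityState, float] | None = None,
    asymptomatic_cost: float = 4946.0,
) -> dict[SeverityState, float]:
    """Derive all five annual state costs from the severe-state anchor.

    Returns costs rounded to the nearest dollar, matching how the
    published table presents them; callers needing unrounded values can
    multiply directly.
    """
    if severe_anchor <= 0:
        raise ValueError("severe-state cost anchor must be positive")
    mult = dict(DEFAULT_COST_MULTIPLIERS if multipliers is None else multipliers)
    missing = {SeverityState.EXTREME, SeverityState.MODERATE, SeverityState.MILD} - set(mult)
    if missing:
        raise ValueError(f"missing cost multipliers for {sorted(s.value for s in missing)}")
    costs = {
        SeverityState.ASYMPTOMATIC: float(asymptomatic_cost),
        SeverityState.MILD: severe_anchor * mult[SeverityState.MILD],
        SeverityState.MODERATE: severe_anchor * mult[SeverityState.MODERATE],
        SeverityState.SEVERE: float(severe_anchor),
        SeverityState.EXTREME: severe_anchor * mult[SeverityState.EXTREME],
    }
    return {s: round(c) for s, c in costs.items()}


def derive_mortality_rrs(base_rr: float) -> dict[SeverityState, float]:
    """Severity-specific mortality RRs from the all-cause PTSD RR.

    Severe sits 10% above the pooled all-cause RR, extreme 10% above
    severe, moderate 10% below the base, and mild a further 15% below
    moderate. Returns unrounded values (round to 2 decimals only for
    reporting).
    """
    if base_rr < 1:
        raise ValueError("base all-cause RR must be >= 1")
    severe = base_rr * 1.1
    moderate = base_rr * 0.9
    return {
        SeverityState.ASYMPTOMATIC: 1.0,
        SeverityState.MILD: moderate * 0.85,
        SeverityState.MODERATE: moderate,
        SeverityState.SEVERE: severe,
        SeverityState.EXTREME: severe * 1.1,
    }


def pool_cost_estimates(estimates: Sequence[tuple[float, float]]) -> float:
    """Pool study cost estimates weighted by sqrt(sample size)."""
    if len(estimates) == 0:
        raise ValueError("need at least one estimate to pool")
    costs = np.array([c for c, _ in estimates], dtype=float)
    ns = np.array([n for _, n in estimates], dtype=float)
    if np.any(ns <= 0) or np.any(costs < 0):
        raise ValueError("sample sizes must be positive and costs non-negative")
    w = np.sqrt(ns)
    return float(np.sum(costs * w) / np.sum(w))


# ---------------------------------------------------------------------------
# Intervention cost
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InterventionCost:
    """Micro-costed per-patient intervention cost."""

    components: dict[str, float]
    total: float

    def share(self, component: str) -> float:
        return self.components[component] / self.total


def total_intervention_cost(components: Mapping[str, float]) -> InterventionCost:
    if any(v < 0 for v in components.values()):
        raise ValueError("component costs must be non-negative")
    comps = {k: float(v) for k, v in components.items()}
    return InterventionCost(components=comps, total=float(sum(comps.values())))


# ---------------------------------------------------------------------------
# Effectiveness
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectivenessSpec:
    """Trial effect size: mean (SD) change in CAPS-IV total score.

    ``sd_caps_change`` is the patient-level SD; the sampling SD of the
    mean (used by probabilistic sensitivity analysis) is sd / sqrt(n).
    """

    mean_caps_change: float = -37.9
    sd_caps_change: float = 28.9
    trial_n: int = 74

    def __post_init__(self) -> None:
        if self.sd_caps_change <= 0:
            raise ValueError("SD of CAPS change must be positive")
        if self.trial_n <= 0:
            raise ValueError("trial sample size must be positive")

    @property
    def sampling_sd(self) -> float:
        """SE of the mean change; reproduces the reported 95% CI low end of -31.3."""
        return self.sd_caps_change / math.sqrt(self.trial_n)


# ---------------------------------------------------------------------------
# Full model parameter set
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelParams:
    bands: SeverityBands
    state_params: dict[SeverityState, StateParams]
    intake_distribution: CohortDistribution
    followup_distribution: CohortDistribution
    intervention_cost: InterventionCost
    effectiveness: EffectivenessSpec
    discount_rate: float
    cohort_size: int
    mean_age: float
    horizon: int
    cost_phase_in: tuple[float, ...]
    life_table: LifeTable
    inflation_multiplier: float = 1.0
    half_cycle_credit: bool = True
    baseline_caps_mean: float = 85.8
    baseline_caps_sd: float = 19.3
    sensitivity: dict[str, Any] = field(default_factory=dict)
    progression: dict[str, Any] = field(default_factory=dict)
    config: dict[str, Any] = field(default_factory=dict, repr=False, compare=False)

    def utilities(self) -> np.ndarray:
        return np.array([self.state_params[s].utility for s in LIVING_STATES])

    def annual_costs(self) -> np.ndarray:
        return np.array([self.state_params[s].annual_cost for s in LIVING_STATES])

    def mortality_rrs(self) -> np.ndarray:
        return np.array([self.state_params[s].mortality_rr for s in LIVING_STATES])

    def with_overrides(self, overrides: Mapping[str, Any]) -> "ModelParams":
        """Rebuild from this parameter set's config with extra overrides."""
        cfg = copy.deepcopy(self.config)
        return build_params(cfg, overrides=overrides, strict=False)


# Override paths: dotted parameter path -> nested config keys.
_RAW_PATHS: dict[str, tuple[str, ...]] = {
    "discount_rate": ("discount_rate",),
    "cohort_size": ("cohort_size",),
    "mean_age": ("mean_age",),
    "horizon": ("horizon",),
    "inflation_multiplier": ("inflation_multiplier",),
    "medical_cost_multiplier": ("medical_cost_multiplier",),
    "half_cycle_credit": ("half_cycle_credit",),
    "intake_rounding": ("intake_rounding",),
    "life_table": ("life_table",),
    "cost_phase_in": ("cost_phase_in",),
    "effectiveness.mean_caps_change": ("effectiveness", "mean_caps_change"),
    "effectiveness.sd_caps_change": ("effectiveness", "sd_caps_change"),
    "effectiveness.trial_n": ("effectiveness", "trial_n"),
    "costs.severe_anchor": ("severe_cost_anchor",),
    "costs.asymptomatic": ("asymptomatic_cost",),
    "mortality.base_rr": ("base_mortality_rr",),
    "progression.rate": ("progression", "rate"),
    "progression.start_cycle": ("progression", "start_cycle"),
}
for _s in LIVING_STATES:
    _RAW_PATHS[f"utilities.{_s.value}"] = ("utilities", _s.value)
for _s in DEFAULT_COST_MULTIPLIERS:
    _RAW_PATHS[f"costs.multiplier.{_s.value}"] = ("cost_multipliers", _s.value)
for _name in ("therapists", "screening_diagnostics", "pharmaceutical"):
    _RAW_PATHS[f"intervention_cost.components.{_name}"] = ("intervention_components", _name)
for _s in LIVING_STATES:
    _RAW_PATHS[f"followup_counts.{_s.value}"] = ("followup_counts", _s.value)

# Paths resolved after derivation rather than on the raw config.
_SPECIAL_PATHS = (
    "intervention_cost.total",  # rescales all components proportionally
    *(f"state_params.{s.value}.mortality_rr" for s in LIVING_STATES),
    *(f"state_params.{s.value}.annual_cost" for s in LIVING_STATES),
    *(f"state_params.{s.value}.utility" for s in LIVING_STATES),
    "followup_distribution",  # a CohortDistribution / mapping, set directly
)


def valid_override_paths() -> list[str]:
    return sorted([*_RAW_PATHS, *_SPECIAL_PATHS])


def _default_config() -> dict[str, Any]:
    text = resources.files("mapcea.data").joinpath("table1_defaults.yaml").read_text()
    return yaml.safe_load(text)


def load_default_params(
    overrides: Mapping[str, Any] | None = None,
    config_path: str | None = None,
) -> ModelParams:
    """The canonical base case, optionally with targeted overrides.

    ``overrides`` maps dotted parameter paths (see
    :func:`valid_override_paths`) to replacement values and is applied
    last. An unknown path raises with the list of valid paths.
    """
    if config_path is None:
        cfg = _default_config()
    else:
        with open(config_path) as fh:
            cfg = yaml.safe_load(fh)
    return build_params(cfg, overrides=overrides, strict=True)


def build_params(
    config: dict[str, Any],
    overrides: Mapping[str, Any] | None = None,
    strict: bool = True,
) -> ModelParams:
    """Construct a :class:`ModelParams` from a raw config mapping.

    ``strict`` enforces the cross-state ordering invariants (utilities
    non-increasing, costs increasing, RRs non-decreasing with severity).
    Sensitivity machinery rebuilds with ``strict=False`` because jointly
    sampled per-state draws can transiently invert adjacent states.
    """
    cfg = copy.deepcopy(config)
    overrides = dict(overrides or {})

    special: dict[str, Any] = {}
    for path, value in overrides.items():
        if path in _RAW_PATHS:
            node = cfg
            *parents, leaf = _RAW_PATHS[path]
            for key in parents:
                node = node.setdefault(key, {})
            node[leaf] = value
        elif path in _SPECIAL_PATHS:
            special[path] = value
        else:
            raise KeyError(
                f"unknown override path {path!r}; valid paths: {', '.join(valid_override_paths())}"
            )

    bands = DEFAULT_BANDS
    validate_bands(bands)

    cohort_size = int(cfg["cohort_size"])
    discount_rate = float(cfg["discount_rate"])
    horizon = int(cfg["horizon"])
    mean_age = float(cfg["mean_age"])
    if cohort_size <= 0:
        raise ValueError("cohort size must be positive")
    if not 0 <= discount_rate <= 0.2:
        raise ValueError("discount rate must lie in [0, 0.2]")
    if horizon < 1:
        raise ValueError("horizon must be at least one year")

    phase_in = tuple(float(f) for f in cfg["cost_phase_in"])
    if any(f2 < f1 for f1, f2 in zip(phase_in, phase_in[1:])) or not all(
        0 <= f <= 1 for f in phase_in
    ):
        raise ValueError("phase-in fractions must be non-decreasing within [0, 1]")

    # Severity distributions. The printed intake counts over-total the
    # cohort by one; the adjusted variant (default) absorbs the
    # correction in the moderate cell.
    rounding = cfg.get("intake_rounding", "adjusted")
    if rounding not in ("adjusted", "printed"):
        raise ValueError("intake_rounding must be 'adjusted' or 'printed'")
    intake_key = "intake_counts_adjusted" if rounding == "adjusted" else "intake_counts_printed"
    intake = CohortDistribution.from_mapping(cfg[intake_key])
    followup = CohortDistribution.from_mapping(cfg["followup_counts"])
    if "followup_distribution" in special:
        fu = special["followup_distribution"]
        followup = fu if isinstance(fu, CohortDistribution) else CohortDistribution.from_mapping(fu)
    # the printed intake counts famously over-total the cohort by one;
    # the 'printed' variant keeps them as published
    if strict and rounding == "adjusted" and intake.total != cohort_size:
        raise ValueError(f"intake distribution totals {intake.total}, expected {cohort_size}")
    if strict and followup.total != cohort_size:
        raise ValueError(f"follow-up distribution totals {followup.total}, expected {cohort_size}")

    # Derived per-state parameters.
    costs = derive_state_costs(
        float(cfg["severe_cost_anchor"]),
        {SeverityState(k): float(v) for k, v in cfg["cost_multipliers"].items()},
        float(cfg["asymptomatic_cost"]),
    )
    rrs = derive_mortality_rrs(float(cfg["base_mortality_rr"]))
    utilities = {SeverityState(k): float(v) for k, v in cfg["utilities"].items()}

    inflation = float(cfg.get("inflation_multiplier", 1.0))
    med_mult = float(cfg.get("medical_cost_multiplier", 1.0))

    state_params: dict[SeverityState, StateParams] = {}
    for s in LIVING_STATES:
        cost = costs[s] * inflation
        if s in SYMPTOMATIC_STATES:
            cost *= med_mult
        state_params[s] = StateParams(
            state=s, utility=utilities[s], annual_cost=cost, mortality_rr=rrs[s]
        )

    for path, value in special.items():
        parts = path.split(".")
        if parts[0] == "state_params":
            s = SeverityState(parts[1])
            state_params[s] = replace(state_params[s], **{parts[2]: float(value)})

    if strict:
        _check_ordering(state_params)

    intervention = total_intervention_cost(cfg["intervention_components"])
    if "intervention_cost.total" in special:
        factor = float(special["intervention_cost.total"]) / intervention.total
        intervention = total_intervention_cost(
            {k: v * factor for k, v in intervention.components.items()}
        )

    eff_cfg = cfg["effectiveness"]
    effectiveness = EffectivenessSpec(
        mean_caps_change=float(eff_cfg["mean_caps_change"]),
        sd_caps_change=float(eff_cfg["sd_caps_change"]),
        trial_n=int(eff_cfg.get("trial_n", 74)),
    )

    table_ref = cfg.get("life_table", "us_lifetable_2007_synthetic.csv")
    life_table = _load_life_table(table_ref)

    caps_cfg = cfg.get("baseline_caps", {})
    return ModelParams(
        bands=bands,
        state_params=state_params,
        intake_distribution=intake,
        followup_distribution=followup,
        intervention_cost=intervention,
        effectiveness=effectiveness,
        discount_rate=discount_rate,
        cohort_size=cohort_size,
        mean_age=mean_age,
        horizon=horizon,
        cost_phase_in=phase_in,
        life_table=life_table,
        inflation_multiplier=inflation,
        half_cycle_credit=bool(cfg.get("half_cycle_credit", True)),
        baseline_caps_mean=float(caps_cfg.get("mean", 85.8)),
        baseline_caps_sd=float(caps_cfg.get("sd", 19.3)),
        sensitivity=cfg.get("sensitivity", {}),
        progression=cfg.get("progression", {}),
        config=cfg,
    )


_TABLE_CACHE: dict[str, LifeTable] = {}


def _load_life_table(ref: str) -> LifeTable:
    if ref not in _TABLE_CACHE:
        try:
            _TABLE_CACHE[ref] = load_bundled_life_table(ref)
        except FileNotFoundError:
            _TABLE_CACHE[ref] = read_life_table(ref)
    return _TABLE_CACHE[ref]


def _check_ordering(state_params: Mapping[SeverityState, StateParams]) -> None:
    u = [state_params[s].utility for s in LIVING_STATES]
    c = [state_params[s].annual_cost for s in LIVING_STATES]
    r = [state_params[s].mortality_rr for s in LIVING_STATES]
    if u[0] != 1.0:
        raise ValueError("asymptomatic utility must be 1.0")
    if any(b > a for a, b in zip(u, u[1:])):
        raise ValueError("utilities must be non-increasing with severity")
    if any(b <= a for a, b in zip(c, c[1:])):
        raise ValueError("annual costs must be strictly increasing with severity")
    if r[0] != 1.0 or any(b < a for a, b in zip(r, r[1:])):
        raise ValueError("mortality RRs must be non-decreasing with severity, 1 when asymptomatic")
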
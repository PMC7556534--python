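"""Publication-style result tables and run provenance helpers."""
from __future__ import annotations

import hashlib
import json
from typing import Any

import pandas as pd

from .outcomes import CEAResult
from .params import ModelParams
from .states import LIVING_STATES


def render_table2(results: list[CEAResult]) -> pd.DataFrame:
    """Cost / QALY / death summary, one row per analytic horizon.

    Money is rounded to whole dollars, QALYs to integers (one decimal
    at fractional horizons, as published), deaths to one decimal. The
    ICER column carries the dominance flag where no ratio is defined.
    """
    if not results:
        raise ValueError("need results for at least one horizon")
    rows = []
    for res in results:
        frac = res.horizon != int(res.horizon)
        q = (lambda v: round(v, 1)) if frac else (lambda v: round(v))
        value = res.icer
        rows.append(
            {
                "horizon_years": res.horizon,
                "cost_map": round(res.cost_map),
                "cost_control": round(res.cost_control),
                "net_cost": round(res.net_cost),
                "qalys_map": q(res.qalys_map),
                "qalys_control": q(res.qalys_control),
                "qalys_gained": q(res.qalys_gained),
                "deaths_map": round(res.deaths_map, 1),
                "deaths_control": round(res.deaths_control, 1),
                "deaths_averted": round(res.deaths_averted, 1),
                "icer": round(value) if isinstance(value, float) else value,
            }
        )
    return pd.DataFrame(rows)


def format_table2(table: pd.DataFrame) -> str:
    """Human-readable rendering of :func:`render_table2` output."""
    out = table.copy()
    for col in ("cost_map", "cost_control", "net_cost"):
        out[col] = out[col].map(lambda v: f"({abs(v):,.0f})" if v < 0 else f"{v:,.0f}")
    out["icer"] = out["icer"].map(lambda v: f"{v:,.0f}" if isinstance(v, (int, float)) else v)
    return out.to_string(index=False)


def resolved_config(params: ModelParams) -> dict[str, Any]:
    """JSON-serialisable snapshot of the resolved parameter set."""
    return {
        "cohort_size": params.cohort_size,
        "mean_age": params.mean_age,
        "horizon": params.horizon,
        "discount_rate": params.discount_rate,
        "inflation_multiplier": params.inflation_multiplier,
        "half_cycle_credit": params.half_cycle_credit,
        "cost_phase_in": list(params.cost_phase_in),
        "intake_distribution": {s.value: params.intake_distribution[s] for s in LIVING_STATES},
        "followup_distribution": {s.value: params.followup_distribution[s] for s in LIVING_STATES},
        "intervention_cost": {
            "components": params.intervention_cost.components,
            "total": params.intervention_cost.total,
        },
        "effectiveness": {
            "mean_caps_change": params.effectiveness.mean_caps_change,
            "sd_caps_change": params.effectiveness.sd_caps_change,
            "trial_n": params.effectiveness.trial_n,
        },
        "state_params": {
            s.value: {
                "utility": params.state_params[s].utility,
                "annual_cost": params.state_params[s].annual_cost,
                "mortality_rr": params.state_params[s].mortality_rr,
            }
            for s in LIVING_STATES
        },
        "life_table_span": [params.life_table.min_age, params.life_table.max_age],
        "life_table_q40": params.life_table.qx[40 - params.life_table.min_age]
        if params.life_table.min_age <= 40 <= params.life_table.max_age
        else None,
    }


def config_hash(params: ModelParams) -> str:
    blob = json.dumps(resolved_config(params), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
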
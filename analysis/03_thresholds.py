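#!/usr/bin/env python
"""Threshold and two-way sensitivity analyses.

Computes (a) the fraction of base-case symptomatic medical costs at
which 30-year net savings vanish, and the ICER when those costs are cut
to 10%; (b) the per-patient intervention cost at which a 5-year horizon
breaks even, and the ICER at a $20,000 intervention cost; (c) a full
MAP-cost x horizon grid. Writes results/thresholds.json and
results/twoway_map_cost_horizon.csv.
"""
import json
from pathlib import Path

import numpy as np

import mapcea as m
from mapcea.sensitivity import evaluate_output

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    params = m.load_default_params()

    cost_mult = m.cost_threshold(params, "medical_cost_multiplier", (0.0, 1.0), horizon=30)
    icer_10pct = evaluate_output(params, {"medical_cost_multiplier": 0.10}, "icer", 30)
    map_cost_5y = m.cost_threshold(params, "intervention_cost.total", (0.0, 30_000.0), horizon=5)
    icer_20k_5y = evaluate_output(params, {"intervention_cost.total": 20_000.0}, "icer", 5)

    thresholds = {
        "medical_cost_multiplier_at_zero_net_cost_30y": cost_mult,
        "icer_at_10pct_medical_costs_30y": icer_10pct,
        "map_cost_break_even_5y": map_cost_5y,
        "icer_at_20000_map_cost_5y": icer_20k_5y,
    }
    (OUT / "thresholds.json").write_text(json.dumps(thresholds, indent=2) + "\n")

    grid = m.two_way(
        params,
        "intervention_cost.total", np.linspace(4_000, 20_000, 9),
        "horizon", np.arange(5, 41, 5),
        "net_cost",
    )
    grid.to_csv(OUT / "twoway_map_cost_horizon.csv", index=False)

    print(
        f"Treatment stops saving money once symptomatic-state medical costs fall to "
        f"{cost_mult:.1%} of base case; at 10% of base costs the ICER is "
        f"${icer_10pct:,.0f}/QALY. Over a 5-year horizon the intervention breaks even "
        f"at ${map_cost_5y:,.0f} per patient; at $20,000 the 5-year ICER is "
        f"${icer_20k_5y:,.0f}/QALY."
    )


if __name__ == "__main__":
    main()
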
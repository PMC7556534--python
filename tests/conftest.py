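import dataclasses

import pytest
from hypothesis import settings

import mapcea as m

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params() -> m.ModelParams:
    return m.load_default_params()


@pytest.fixture(scope="session")
def base_run(params):
    """Both arms at the 30-year base case (shared across tests)."""
    traj_map, traj_control = m.run_comparison(params, horizon=30)
    return params, traj_map, traj_control


@pytest.fixture(scope="session")
def records(params):
    spec = m.CohortSpec(
        baseline_mean=params.baseline_caps_mean,
        baseline_sd=params.baseline_caps_sd,
        effect=params.effectiveness,
        n=params.cohort_size,
    )
    return m.calibrate_cohort(
        params.intake_distribution, params.followup_distribution, spec, seed=0
    )


def make_toy_params(
    base: m.ModelParams,
    q: float = 0.01,
    utilities: dict | None = None,
    costs: dict | None = None,
    rrs: dict | None = None,
    r: float = 0.0,
    half_cycle_credit: bool = True,
) -> m.ModelParams:
    """Small-model builder: flat background mortality plus targeted
    per-state parameter overrides, for hand-checkable scenarios."""
    overrides: dict = {"discount_rate": r, "half_cycle_credit": half_cycle_credit}
    for name, mapping in (("utility", utilities), ("annual_cost", costs), ("mortality_rr", rrs)):
        for state, value in (mapping or {}).items():
            overrides[f"state_params.{state}.{name}"] = value
    p = base.with_overrides(overrides)
    flat = m.LifeTable(ages=list(range(0, 201)), qx=[q] * 201)
    return dataclasses.replace(p, life_table=flat)
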
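"""Probabilistic sensitivity analysis (Monte Carlo).

Each iteration draws all parameter distributions jointly but
independently, rebuilds the derived parameters, runs both arms at the
analytic horizon, and records net cost, QALYs gained and deaths
averted. A master seed spawns one substream per iteration, so results
are bit-for-bit reproducible and invariant to scheduling.

Distribution families follow the published choices: beta for
probabilities and range-specified inputs (a symmetric Beta(4,4)
rescaled to the range, since only ranges are printed), gamma for costs,
lognormal for relative risks, normal for the effectiveness mean — all
parameterised by method of moments. State medical costs carry a printed
SD of $0 and are held fixed unless the caller supplies specs.

The effectiveness draw is a mean CAPS change sampled with the SE of the
trial mean (patient SD / sqrt(n), giving the reported 95% CI of the
mean, -44.5 to -31.3) and is mapped to a severity distribution through
the synthetic cohort.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .outcomes import compare, run_comparison
from .params import ModelParams
from .sensitivity import rebuild_params, reference_records
from .states import LIVING_STATES

Family = Literal[
    "beta-by-range", "gamma-by-moments", "lognormal-by-moments", "normal-by-moments", "fixed"
]


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling recipe for one parameter path."""

    path: str
    family: Family
    mean: float | None = None
    sd: float | None = None
    low: float | None = None
    high: float | None = None
    base: float | None = None
    truncate: tuple[float | None, float | None] = (None, None)

    def __post_init__(self) -> None:
        if self.family == "beta-by-range":
            if self.low is None or self.high is None or not self.low < self.high:
                raise ValueError(f"{self.path}: beta-by-range needs low < high")
        elif self.family == "fixed":
            if self.base is None:
                raise ValueError(f"{self.path}: fixed spec needs a base value")
        else:
            if self.mean is None or self.sd is None or self.sd <= 0:
                raise ValueError(f"{self.path}: {self.family} needs mean and SD > 0")
            if self.family in ("gamma-by-moments", "lognormal-by-moments") and self.mean <= 0:
                raise ValueError(f"{self.path}: {self.family} needs a positive mean")


def sample(spec: DistributionSpec, rng: np.random.Generator) -> float:
    """One draw from ``spec`` (rejection sampling for truncation)."""
    for _ in range(10_000):
        value = _draw(spec, rng)
        lo, hi = spec.truncate
        if (lo is None or value >= lo) and (hi is None or value <= hi):
            return float(value)
    raise RuntimeError(f"{spec.path}: truncation bounds reject all draws")


def _draw(spec: DistributionSpec, rng: np.random.Generator) -> float:
    if spec.family == "fixed":
        return spec.base  # type: ignore[return-value]
    if spec.family == "beta-by-range":
        return spec.low + (spec.high - spec.low) * rng.beta(4.0, 4.0)  # type: ignore[operator]
    m, sd = spec.mean, spec.sd  # type: ignore[assignment]
    if spec.family == "normal-by-moments":
        return rng.normal(m, sd)
    if spec.family == "gamma-by-moments":
        shape = (m / sd) ** 2
        return rng.gamma(shape, sd**2 / m)
    if spec.family == "lognormal-by-moments":
        sigma2 = np.log1p((sd / m) ** 2)
        mu = np.log(m) - sigma2 / 2
        return rng.lognormal(mu, np.sqrt(sigma2))
    raise ValueError(f"unknown family {spec.family!r}")  # pragma: no cover


def default_psa_specs(
    params: ModelParams, mode: Literal["all", "effectiveness"] = "all"
) -> list[DistributionSpec]:
    """The published distribution assignments for the base-case PSA."""
    eff = params.effectiveness
    specs = [
        DistributionSpec(
            "effectiveness.mean_caps_change",
            "normal-by-moments",
            mean=eff.mean_caps_change,
            sd=eff.sampling_sd,
        )
    ]
    if mode == "effectiveness":
        return specs
    sens = params.sensitivity
    rel = float(sens.get("intervention_cost_rel_range", 0.30))
    total = params.intervention_cost.total
    specs.append(
        DistributionSpec(
            "intervention_cost.total", "beta-by-range", low=total * (1 - rel), high=total * (1 + rel)
        )
    )
    lo, hi = sens.get("discount_rate_range", [0.023, 0.038])
    specs.append(DistributionSpec("discount_rate", "beta-by-range", low=float(lo), high=float(hi)))
    lo, hi = sens.get("mean_age_range", [35, 45])
    specs.append(DistributionSpec("mean_age", "beta-by-range", low=float(lo), high=float(hi)))
    u_ranges = sens.get("utility_ranges", {})
    for s in LIVING_STATES[1:]:
        u = params.state_params[s].utility
        if s.value in u_ranges:
            lo, hi = u_ranges[s.value]
        else:
            rel_u = float(u_ranges.get(f"{s.value}_rel", 0.10))
            lo, hi = u * (1 - rel_u), min(1.0, u * (1 + rel_u))
        specs.append(
            DistributionSpec(f"state_params.{s.value}.utility", "beta-by-range", low=lo, high=hi)
        )
    rr_sds = sens.get("rr_sds", {})
    for s in LIVING_STATES[1:]:
        rr = params.state_params[s].mortality_rr
        sd = float(rr_sds.get(s.value, 0.0))
        if sd > 0:
            specs.append(
                DistributionSpec(
                    f"state_params.{s.value}.mortality_rr",
                    "lognormal-by-moments",
                    mean=rr,
                    sd=sd,
                )
            )
    return specs


def spec_hash(specs: list[DistributionSpec]) -> str:
    payload = json.dumps(
        [
            [s.path, s.family, s.mean, s.sd, s.low, s.high, s.base, list(s.truncate)]
            for s in specs
        ],
        sort_keys=False,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PSAResult:
    """Per-iteration draws and outputs, plus provenance."""

    draws: pd.DataFrame
    seed: int
    n_iter: int
    horizon: int
    spec_hash: str
    failures: list[tuple[int, str]] = field(default_factory=list)

    def percentile_summary(self, level: float = 0.90) -> dict[str, dict[str, float]]:
        out = {}
        for col in ("net_cost", "qalys_gained", "deaths_averted"):
            lo, hi = percentile_interval(self.draws[col].to_numpy(), level)
            out[col] = {
                "mean": float(self.draws[col].mean()),
                "low": lo,
                "high": hi,
                "level": level,
            }
        return out


def run_psa(
    params: ModelParams,
    specs: list[DistributionSpec],
    n_iter: int,
    seed: int,
    horizon: int | None = None,
) -> PSAResult:
    """Monte Carlo over ``specs``; reproducible given (seed, n_iter)."""
    if n_iter < 1:
        raise ValueError("need at least one iteration")
    h = params.horizon if horizon is None else horizon
    needs_records = any(s.path == "effectiveness.mean_caps_change" for s in specs)
    records = reference_records(params) if needs_records else None

    streams = np.random.SeedSequence(seed).spawn(n_iter)
    rows: list[dict] = []
    failures: list[tuple[int, str]] = []
    for i in range(n_iter):
        rng = np.random.default_rng(streams[i])
        drawn = {s.path: sample(s, rng) for s in specs}
        try:
            p, scenario = rebuild_params(params, drawn, records)
            traj_map, traj_control = run_comparison(p, horizon=h, scenario=scenario)
            res = compare(traj_map, traj_control, h)
        except Exception as exc:  # recorded, not silently dropped
            failures.append((i, repr(exc)))
            continue
        rows.append(
            {
                "iteration": i,
                **drawn,
                "net_cost": res.net_cost,
                "qalys_gained": res.qalys_gained,
                "deaths_averted": res.deaths_averted,
            }
        )
    if failures and not rows:
        raise RuntimeError(f"every PSA iteration failed; first: {failures[0]}")
    return PSAResult(
        draws=pd.DataFrame(rows),
        seed=seed,
        n_iter=n_iter,
        horizon=h,
        spec_hash=spec_hash(specs),
        failures=failures,
    )


def percentile_interval(samples: np.ndarray, level: float) -> tuple[float, float]:
    """Central empirical interval at ``level`` (linear interpolation)."""
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2:
        raise ValueError("need at least two samples")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    alpha = (1 - level) / 2
    lo, hi = np.quantile(samples, [alpha, 1 - alpha])
    return float(lo), float(hi)
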
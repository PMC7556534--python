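"""Synthetic patient-level CAPS-IV records.

Trial microdata are not deposited, but the model's effectiveness
sensitivity needs a mapping from "mean CAPS change" to a severity
distribution. This module builds a synthetic cohort of (baseline,
follow-up) CAPS-IV scores whose band classification reproduces the
published intake and follow-up distributions *exactly*, and defines the
declared convention for shifting effectiveness:

* baseline scores are drawn per intake band from a truncated normal
  (cohort mean 85.8, SD 19.3) clipped to the band;
* follow-up scores are drawn uniformly within bands sized to the
  follow-up counts, then paired to baselines by severity rank (most
  severe baseline with most severe follow-up), clipping same-band pairs
  so no patient worsens;
* a new mean change m rescales each patient's improvement:
  f' = b + (m / m0) * (f - b), floored at 0, with m0 the nominal
  base-case change (-37.9). m = m0 reproduces the calibrated follow-up
  distribution; m = 0 reproduces the intake distribution exactly.

Records round-trip through CSV (patient_id, baseline_caps,
followup_caps) so real microdata could be substituted without code
changes.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .params import DEFAULT_BANDS, EffectivenessSpec, SeverityBands, classify_caps
from .states import LIVING_STATES, CohortDistribution, SeverityState

#: Practical ceiling for open-ended extreme-band sampling when a record
#: has no paired baseline to bound it (CAPS-IV totals top out at 136).
_EXTREME_CEILING = 136.0


@dataclass(frozen=True)
class CohortSpec:
    """Marginal moments of the trial cohort's CAPS-IV scores."""

    baseline_mean: float = 85.8
    baseline_sd: float = 19.3
    effect: EffectivenessSpec = EffectivenessSpec()
    n: int = 1000

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("cohort size must be positive")
        if self.baseline_sd <= 0:
            raise ValueError("baseline SD must be positive")


def _band_bounds(state: SeverityState, bands: SeverityBands) -> tuple[float, float]:
    for lo, hi, s in bands:
        if s == state:
            # continuous sampling interval [lo, hi+1) floors into the band
            return float(lo), float(hi) + 1.0 if math.isfinite(hi) else math.inf
    raise ValueError(f"state {state} not in bands")


def _counts_vector(dist: CohortDistribution | dict) -> np.ndarray:
    if not isinstance(dist, CohortDistribution):
        dist = CohortDistribution.from_mapping(dist)
    counts = dist.counts
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("calibration needs integer band counts")
    return np.round(counts).astype(int)


def calibrate_cohort(
    intake_counts: CohortDistribution | dict,
    followup_counts: CohortDistribution | dict,
    spec: CohortSpec = CohortSpec(),
    seed: int = 0,
    bands: SeverityBands = DEFAULT_BANDS,
) -> pd.DataFrame:
    """Generate patient records matching both severity snapshots exactly.

    Returns a DataFrame with columns (patient_id, baseline_caps,
    followup_caps), sorted by descending baseline severity. Raises if
    the two snapshots cannot be realised for ``spec.n`` patients.
    """
    intake = _counts_vector(intake_counts)
    followup = _counts_vector(followup_counts)
    n = int(intake.sum())
    if n != spec.n or int(followup.sum()) != spec.n:
        raise ValueError(
            f"snapshot counts must each total n={spec.n} "
            f"(got intake {intake.sum()}, follow-up {followup.sum()})"
        )
    rng = np.random.default_rng(seed)

    # Baseline: truncated normal within each occupied intake band.
    baseline_parts = []
    for state, k in zip(LIVING_STATES, intake):
        if k == 0:
            continue
        lo, hi = _band_bounds(state, bands)
        a = (lo - spec.baseline_mean) / spec.baseline_sd
        b = (hi - spec.baseline_mean) / spec.baseline_sd if math.isfinite(hi) else np.inf
        draws = stats.truncnorm.rvs(
            a, b, loc=spec.baseline_mean, scale=spec.baseline_sd, size=k, random_state=rng
        )
        baseline_parts.append(draws)
    baseline = np.sort(np.concatenate(baseline_parts))[::-1]

    # Follow-up band of each record, by severity rank (most severe
    # baseline -> most severe follow-up band).
    fu_state_idx = np.repeat(np.arange(len(LIVING_STATES))[::-1], followup[::-1])
    b_state_idx = np.array([classify_caps(b, bands).rank for b in baseline])

    followup_scores = np.empty(n)
    u = rng.random(n)
    for i in range(n):
        lo, hi = _band_bounds(LIVING_STATES[fu_state_idx[i]], bands)
        upper = hi if math.isfinite(hi) else _EXTREME_CEILING
        if fu_state_idx[i] == b_state_idx[i]:
            # same band: cap at the baseline so no patient worsens
            upper = min(upper, baseline[i])
        if upper <= lo:
            followup_scores[i] = min(baseline[i], lo)
        else:
            followup_scores[i] = lo + (upper - lo) * u[i]

    records = pd.DataFrame(
        {
            "patient_id": np.arange(n),
            "baseline_caps": baseline,
            "followup_caps": followup_scores,
        }
    )
    for snapshot, expected in (("baseline", intake), ("followup", followup)):
        got = distribution_from_records(records, snapshot, bands).counts
        if not np.array_equal(np.round(got).astype(int), expected):
            raise ValueError(f"infeasible counts: calibrated {snapshot} snapshot mismatch")
    return records


def _classify_counts(scores: np.ndarray, bands: SeverityBands) -> np.ndarray:
    """Vectorised band classification -> per-state counts."""
    if np.any(scores < 0):
        raise ValueError("CAPS scores must be non-negative")
    edges = np.array([lo for lo, _, _ in bands[1:]], dtype=float)
    idx = np.digitize(np.floor(scores), edges)
    return np.bincount(idx, minlength=len(LIVING_STATES)).astype(float)


def distribution_from_records(
    records: pd.DataFrame,
    snapshot: Literal["baseline", "followup"],
    bands: SeverityBands = DEFAULT_BANDS,
) -> CohortDistribution:
    """Band-classify one snapshot of the records and count."""
    if len(records) == 0:
        raise ValueError("no records to classify")
    col = {"baseline": "baseline_caps", "followup": "followup_caps"}[snapshot]
    return CohortDistribution(_classify_counts(records[col].to_numpy(), bands))


def apply_effect_shift(
    records: pd.DataFrame,
    new_mean_change: float,
    base_mean_change: float = -37.9,
    bands: SeverityBands = DEFAULT_BANDS,
) -> CohortDistribution:
    """Severity distribution implied by a different mean CAPS change.

    Rescales every patient's improvement by ``new / base`` relative to
    their baseline score, floors at zero, and reclassifies. This is the
    CAPS -> distribution mapping behind the effectiveness tornado bars
    and the probabilistic effectiveness sweep.
    """
    if base_mean_change == 0:
        raise ValueError("base mean change must be non-zero")
    factor = new_mean_change / base_mean_change
    b = records["baseline_caps"].to_numpy()
    f = records["followup_caps"].to_numpy()
    shifted = np.maximum(0.0, b + factor * (f - b))
    return CohortDistribution(_classify_counts(shifted, bands))


def write_records(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False)


def read_records(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"patient_id", "baseline_caps", "followup_caps"}
    if not required.issubset(df.columns):
        raise ValueError(f"records CSV needs columns {sorted(required)}")
    if (df["baseline_caps"] < 0).any() or (df["followup_caps"] < 0).any():
        raise ValueError("CAPS scores must be non-negative")
    return df
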
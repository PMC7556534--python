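# Methods

## Model structure

A deterministic Markov cohort model with annual cycles. The state space
is five living CAPS-IV severity bands (asymptomatic 0–19, mild 20–39,
moderate 40–59, severe 60–79, extreme ≥80; integer-score convention,
non-integer scores floored) plus an absorbing dead state. Two arms are
compared for the same 1,000 patients:

- **control** — the cohort at intake: (0, 0, 121, 311, 568) across the
  five states, no upfront cost;
- **MAP** — the same cohort at post-treatment follow-up:
  (216, 270, 135, 230, 149), carrying the upfront intervention cost
  ($7,544/patient, the sum of the micro-costed components) at t = 0,
  undiscounted.

In the base case there are no transitions between living states: the
treatment effect is entirely the difference between the two starting
distributions, held for the analytic horizon. The only base-case
transition is death, at `q(age) × RR_state`, clamped at 1 with a
warning if a pathological input overflows. Fractional persons are
carried exactly; this is a cohort model, not a microsimulation.

The printed intake counts (122, 311, 568) total 1,001; the default
`adjusted` variant absorbs the correction in the moderate cell
(121), and `intake_rounding: printed` keeps the raw counts (the arm
comparison then tolerates the 0.1% cohort-size mismatch). The two
variants differ by <0.1% in every reported output.

## Accounting conventions

- **Discounting**: end-of-cycle; cycle-t flows are divided by
  (1+r)^t with r = 3%/yr. Chosen because it reproduces the published
  1-year control-arm QALY total (≈445) from the published utilities; no
  additional half-cycle correction on discounting.
- **Decedent credit**: patients dying in a cycle receive half a year of
  utility and medical cost (standard half-cycle convention;
  `half_cycle_credit: false` switches to zero credit — the two differ
  by ≈0.1% on every headline output).
- **Cost phase-in**: chronic-condition spending does not fall the
  moment symptoms do. The MAP arm's cycle-t medical cost is
  `(1−f_t)·C_intake(t) + f_t·C_actual(t)`, where `C_intake(t)` prices
  the arm's current survivor person-years at the intake distribution's
  per-capita cost mix, `C_actual(t)` prices them at their actual
  states, and f = (0, 0.25, 0.50, 0.75, 1.0, 1.0, …). Mortality and
  QALYs always follow the actual post-treatment states — only costs are
  phased.
- **Deaths** are reported undiscounted at every horizon.
- Monetary arithmetic is unrounded internally; rounding (dollars,
  integer QALYs, one-decimal deaths) happens only in the report layer.
- Fractional horizons (the break-even row) interpolate all cumulative
  quantities linearly within the bracketing cycle, consistently across
  costs, QALYs and deaths.

## Parameters

All money in 2019 USD; `inflation_multiplier` (default 1) is a plain
scalar hook — price-index construction is out of scope.

| input | base | notes |
|---|---|---|
| state utilities | 1 / 0.97 / 0.851 / 0.477 / 0.369 | anxiety-disorder utilities; extreme from a veteran cohort |
| state annual costs | $4,946 / $9,944 / $14,916 / $19,888 / $23,866 | derived: mild = 0.5×severe, moderate = 0.75×, extreme = 1.2×; severe anchor pooled from published studies by √n weighting |
| mortality RRs | 1 / 1.74 / 2.05 / 2.51 / 2.76 | derived from all-cause RR 2.28 (severe = 1.1×base, extreme = 1.1×severe, moderate = 0.9×base, mild = 0.85×moderate); unrounded values used internally |
| intervention cost | $6,194 + $997 + $353 = $7,544 | micro-costed; printed total $7,543 reflects component rounding |
| effect size | −37.9 (patient SD 28.9, n = 74) | mean CAPS-IV change; SE of the mean 28.9/√74 ≈ 3.36 |
| discount rate | 3% (2.3–3.8%) | |
| mean age / horizon | 40 yr / 30 yr | cohort ages one year per cycle |

The severe-cost anchor appears in two published variants ($19,888 in
the input table, $19,899 in the text); the default is the table value,
which regenerates the other printed state costs exactly; the text value
is available via `costs.severe_anchor`.

## Background mortality

The engine multiplies severity RRs onto an age-specific background
schedule `q(age)` supplied as a two-column CSV (exact lookup at integer
ages, floor for fractional ages, clamp beyond the last row). The
bundled default, `us_lifetable_2007_synthetic.csv`, is a **synthetic**
Gompertz schedule `q(a) = 0.00139·e^{0.085(a−40)}` on ages 20–110,
calibrated to the published anchor q(40) = 0.00139 (the 2007 U.S.
female value) and tracking the adult U.S. female schedule to within
roughly 10% over ages 40–80. The schedule behind the published death
counts is not recoverable: the published 1-year deaths (6.3 control,
4.3 treated) imply an effective background rate about twice the printed
anchor, and the two arms imply *different* rates, so the schedule is
treated as the least-constrained input, swappable via the `life_table`
config key. Death outputs are validated for sign and ordering, not
level.

## Synthetic patient cohort

Trial microdata are not available, so effectiveness sweeps need a
declared mapping from "mean CAPS change" to a severity distribution.
The synthetic cohort:

1. samples each patient's baseline CAPS from a truncated normal
   (mean 85.8, SD 19.3) within their intake band;
2. assigns follow-up bands by severity rank (most severe baseline →
   most severe follow-up band), sampling uniformly within the band and
   capping same-band pairs at the baseline so no patient worsens;
3. for a new mean change m, rescales each patient's improvement:
   `f' = max(0, b + (m/m₀)(f−b))` with m₀ = −37.9, then reclassifies.

By construction the calibrated records reproduce **both** printed
severity distributions exactly for every seed, m = m₀ returns exactly
the follow-up distribution, m = 0 returns exactly the intake
distribution, and a more negative m never shifts mass toward worse
states (first-order stochastic dominance). The rescaling form was
chosen over a uniform additive shift because an additive shift cannot
satisfy the m = 0 full-reversal limit. The realised mean change of the
calibrated records (≈ −35, within the marginals' constraints) is a
consistency check, not a target; the mapping treats m₀ as the nominal
base-case effect. What the cohort does *not* emulate: within-band score
shapes (uniform by assumption), baseline–follow-up correlation beyond
rank pairing, covariates, or the trial's control arm. Passing tests
therefore show the model's *mapping* behaves coherently, not that real
patients move this way.

## Sensitivity analyses

- **One-way (tornado)**: each input to its low/high bound, others at
  base; sorted by span of 30-year net cost. Utilities get their stated
  ranges (mild 0.90–1.00, others ±10% capped at 1), RRs mean ± 1.96 SD
  clipped at 1, discount 2.3–3.8%, age 35–45, intervention cost ±30%.
  The published inputs list no deterministic range for medical costs
  (their PSA SD is $0, i.e. held fixed); the tornado uses a ±30%
  multiplier on symptomatic-state costs, mirroring the intervention
  band — with it, medical-cost scaling is the top driver, matching the
  published ranking.
- **Threshold search**: Brent root-finding (rtol 1e-6) on any knob with
  a sign change over its bracket, e.g. the symptomatic-cost multiplier
  at which 30-year net cost crosses zero (→ 19.3%).
- **Two-way**: full-factorial grids, e.g. intervention cost ($4k–$20k)
  × horizon (5–40 yr).
- **Relapse scenario**: treated-arm survivors progress one severity
  step per year with probability p (default 6%, range 0–12%; a 5%/0–10%
  variant is kept in config) from the end of year 5 onward; extreme
  patients progress no further. Progression applies to all non-extreme
  living states — it is erosion of treatment benefit, so previously
  recovered (asymptomatic) patients relapse too. Controls, already
  chronic and stable by inclusion criteria, are unaffected.
- **PSA**: 10,000 iterations; each draws all distribution specs
  independently (no published correlation structure), rebuilds derived
  parameters, and runs both arms at 30 years. Families: symmetric
  Beta(4,4) rescaled to the range for range-only inputs (keeps mass
  centred with soft tails; isolated in one function), gamma and
  lognormal by method of moments for costs and RRs, normal for the
  effectiveness mean. The effectiveness draw uses the SE of the trial
  mean (28.9/√74 ≈ 3.36), which reproduces the published 95% CI low end
  of −31.3 and the "all iterations remain cost-saving" behaviour; the
  patient-level SD (28.9) would make ~10% of draws show no benefit and
  is not the published sampling spread. A master seed spawns
  per-iteration substreams, so runs are bit-for-bit reproducible and
  schedule-invariant; iteration failures are recorded, never dropped.
  Per-state parameter draws are sampled independently, so the strict
  cross-state ordering checks applied to the base case are relaxed
  inside PSA rebuilds.

## Numerical and degenerate-input choices

- Death probabilities `q·RR` clamp at 1 (logged); ages beyond the life
  table clamp to its last row; ages below its first row are an error.
- ICERs are only formed when both increments are positive; cheaper/
  more-effective is "dominant", costlier/less-effective "dominated",
  anything involving a zero increment "indeterminate" (never a
  division by zero).
- Break-even returns `None` (not an exception) when savings never
  cover the upfront cost.
- Problem sizes: 30 annual cycles per arm per evaluation (a single
  comparison runs in ~2 ms), 10,000 PSA iterations, 25-point scenario
  sweeps — the full analysis suite completes in a couple of minutes on
  one core.

## Known limitations

- The model reproduces the published 1-year, 10-year and 30-year
  cost/QALY results within a few percent, but the published 3.1-year
  break-even is not recoverable from the published inputs: with the
  stated 0/25/50/75/100 phase-in and state costs, discounted savings by
  year 3.1 cannot reach the intervention cost, and the model breaks
  even near 3.5 years. The package reports what the inputs imply.
- Death *levels* inherit the uncertainty of the background schedule
  (see above); only signs and orderings are meaningful.
- Payer perspective only: productivity, disability payments, family and
  criminal-justice effects are excluded, so societal benefits are
  understated.
- No remission in either arm and no relapse in the base case; the
  relapse scenario bounds the latter assumption.
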
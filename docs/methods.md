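# Methods

## Model structure

The model is a two-state (alive/dead) Markov cohort model for patients
with mild TBI plus intracranial bleeding or moderate TBI, treated with
versus without tranexamic acid on top of standard care. The cohort enters
alive at exactly age 42.0 (the mean trial age; no age distribution is
modelled). Cycles are daily for the first year — so the 28-day trial
mortality is resolved at the resolution it was observed — and annual
thereafter until the terminal age.

Three competing exits are tracked. During days 1–28 the arms carry
constant daily hazards obtained by inverting the 28-day cumulative risks,
`h = 1 − (1 − p₂₈)^(1/28)`; the treated arm's head-injury risk is the
cumulative risk multiplied by the risk ratio *before* daily conversion,
because the trial effect is a 28-day cumulative-incidence ratio. The
distribution of deaths within the 28 days is not reported, so a constant
hazard is a modelling choice. General-population background mortality is
*not* added during the trial window — trial deaths already include all
causes — and begins on day 29 as `min(1, SMR₁ · q₄₂)` converted to a
daily probability; annual cycles from year 2 apply `min(1, SMR₂ · qₓ)`
with the cohort ageing one year per cycle. Within a cycle, exits combine
as independent risks (`p_total = 1 − Π(1 − p_cause)`) with deaths
attributed to causes in proportion to their hazards; at these hazard
magnitudes the attribution convention changes nothing at the 4th decimal.

No half-cycle correction is applied: daily cycles make it irrelevant in
year one, and for the annual tail the end-of-cycle occupancy convention
slightly understates life-years identically in both arms, which largely
cancels in the increment.

## Parameters

All parameters live in a catalogue of tagged distributions
(`src/tbicea/data/base_case_parameters.yaml`); point estimates are the
distribution means (beta, gamma, normal) or `exp(μ)` (lognormal).

| Parameter | UK | Pakistan | Distribution |
|---|---|---|---|
| 28-day head-injury death risk | 0.061 | 0.079 | Beta(42, 643) / Beta(165, 1919) |
| 28-day non-head-injury death risk | 0.018 | 0.005 | Beta(12, 673) / Beta(11, 2073) |
| Head-injury risk ratio (treated) | 0.78 | 0.78 | LogNormal(−0.248, 0.1) |
| SMR year 1 / later | 4.00 / 2.26 | same | Normal from 95% CI |
| Entry utility (weighted GOS) | 0.747 | same | by component |
| Discount rate | 3.5%/yr | 3%/yr | fixed |
| Threshold per QALY | £20 000 | US$158 | fixed |

Beta risk specifications are `(events, non-events)`, so `α + β` equals
the trial arm size. SMR uncertainty uses a symmetric normal built from
the printed 95% CI (`sd = (hi − lo)/3.92`) even though the printed
intervals are slightly asymmetric, because that is how the distribution
is declared in the source table. The vegetative-state utility (−0.178)
is held fixed in probabilistic analyses: no valid beta distribution
exists for a negative value and its cohort weight is 124/5183.

The UK hourly staff cost behind the 21-minute administration time is not
published; the default is £37/hour (a typical 2018 unit-cost-compendium
hospital-nurse rate), configurable via `build_base_case(...,
admin_hourly_rate=...)`. Pakistan uses the published US$5.20/hour
(→ US$1.82). The UK length-of-stay gamma (k=31.4, θ=0.43) has mean
13.50 days while the printed stay is 13.7 days; the distribution is used
for sampling and 13.7 for deterministic costing, with hospital cost
carried as per-day cost × stay so the printed totals (£4741 / US$92) are
reproduced exactly and arm-specific-stay scenarios rescale cleanly.

## Valuation

Discounting is continuous-time, `(1 + r)^{−t}` at each cycle's start
(daily cycles use `t = day/365`), applied equally to costs and outcomes.
QALYs weight occupancy by the entry utility times an age multiplier
normalised to 1 at age 42; patients dying within the trial window accrue
zero utility between injury and death (implemented by crediting days
1–28 only to the fraction alive at day 28). The bundled age-multiplier
table declines linearly by 0.004 per year of age beyond 42 — a stand-in
with the shape of published population utility norms, whose exact values
are not public; it can be replaced by any `age,multiplier` CSV.

Costs: treatment components (drug £6.00/US$1.92, fluids, consumables,
administration) are a time-0 lump in the treated arm only; the hospital
stay is a time-0 lump in both arms (stay occurs within the first month,
so within-stay discounting is negligible). UK monitoring costs are
survivor-conditioned — higher survival drives higher monitoring spend —
with the first-year amount (£11 662) spread uniformly over days 29–365 in
proportion to the cohort alive and the annual amount (£2505) accrued at
each annual cycle until death or the configured duration (lifetime by
default; 1-year and 5-year limits are scenario switches). Pakistan has no
post-discharge monitoring costs.

## Background mortality

National life tables are not redistributable inputs here, so the package
bundles synthetic tables built from a Gompertz–Makeham hazard
`h(age) = c + a·e^{b·age}`, `qx = 1 − e^{−h}`, with the terminal age
(default 100, a closure the source analysis does not state) forced to
`qx = 1`. The constants were calibrated once to published demographic
anchors and then frozen:

- UK-like: `c = 3.0e−4, a = 1.45e−5, b = 0.100` → q₄₂ ≈ 0.0016,
  e₀ ≈ 81.5 y, e₄₂ ≈ 40.7 y.
- Pakistan-like: `c = 2.0e−3, a = 8.0e−5, b = 0.087` → q₄₂ ≈ 0.005,
  e₀ ≈ 68.4 y, e₄₂ ≈ 32.0 y.

A Gompertz–Makeham fit has no infant-mortality hump, which is irrelevant
here because the cohort enters at 42. Users can substitute a real
national table (`age,qx` CSV) via `read_life_table` or the CLI's
`--life-table` flag; results with the synthetic tables should be read as
approximations of the published ones at the few-percent level, and tests
against published ICERs therefore use a ±15% band.

## Sensitivity analyses

The PSA draws every uncertain parameter independently once per
simulation (the source analysis states only that distributions were
sampled simultaneously; no correlation structure is imposed) and runs
both arms with the shared draw. The headline PSA ICER is the
ratio-of-means `mean(ΔC)/mean(ΔQ)`, which is stable when an occasional
draw has ΔQ near zero; the mean of per-simulation ratios is also
computed and reported for reference. The probability of
cost-effectiveness is the fraction of draws with positive incremental
net monetary benefit at the country threshold, and the CEAC evaluates
this on a grid from 0 to twice the threshold.

One-way deterministic scenarios: risk ratio at its CI bounds (0.64,
0.95) and the 30-minute-treatment value 0.62; both-arm utilities 0.63
and 0.79; arm-specific utilities 0.74 (treated) vs 0.75 (control);
monitoring limited to 1 or 5 years; discounting at 0% and 6%; excess
mortality removed (both SMRs set to 1); arm-specific length of stay
(UK 14.0/13.3 d, Pakistan 7.3/7.4 d); and a 5-year horizon. The
arm-specific-utility scenario is extremely sensitive to the utility
decrement: at the two-decimal published values (0.74/0.75) the QALY gain
nearly vanishes and the ICER rises to ~£75 000 (UK) / ~US$79 (Pakistan);
this package applies the published values as printed rather than any
back-solved higher-precision pair.

## Synthetic trials and parameter recovery

`synthetic_trial` simulates a two-arm 28-day trial as one multinomial
per arm over (head death, non-head death, survive) — preserving binomial
margins while keeping counts summing to the arm size — with survivor
disability drawn from a multinomial over the published GOS mix
(3094:1288:677:124). Estimation maps control-arm counts to
`Beta(deaths, n − deaths)` and the risk ratio to
`LogNormal(log(p̂₁/p̂₀), √(1/d₁ − 1/n₁ + 1/d₀ − 1/n₀))`, with no
continuity correction (zero-death arms raise an explicit error).
`recovery_study` runs replicate trials under independent child seeds and
reports estimator bias and 95%-CI coverage. The generator reproduces the
*statistical structure* the model assumes — it does not emulate
covariates, recruitment, time-to-event detail or missingness, so passing
recovery tests demonstrate internal consistency of the estimation chain,
not robustness to real-trial complications.

## Problem sizes and numerics

A lifetime run is 365 daily + 58 annual cycles per arm and takes ~0.2 ms;
the PSA uses 1000 simulations (the source analysis' size) and the
recovery study 200 replicates at 10 000 per arm — chosen as the sizes the
analysis itself reports. Mass conservation in the engine holds to 10⁻¹²
by attributing the residual of the hazard-proportional split to the
background cause. Probabilities are capped at 1 wherever an SMR multiple
exceeds it; degenerate inputs (cumulative risk of 1, zero GOS counts,
non-contiguous life tables, out-of-range rates) raise errors rather than
propagate.

## Known limitations

- Two states only: the disability mix is frozen at its 28-day value, so
  long-term functional change is not modelled.
- The synthetic life tables and age-utility curve are calibrated
  approximations; headline ICERs move by a few percent under the real
  national inputs.
- Health-service perspective: caregiver burden and out-of-pocket costs
  are out of scope by design.
- Severe-TBI and pupil-reactive populations are supported generically
  through configuration, but their parameter values are not bundled.
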
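# Methods

## Model structure and assumptions

The model is a static, deterministic expected-value calculation for a
single birth cohort. Infants are assumed independent and characterized by
one binary exposure (breastfed vs formula-fed at the disease-relevant time
point); disease risk depends only on that exposure; care use and cost per
case are population averages. Feeding rates do not vary over time, partial
breastfeeding is not a separate category, and diseases do not interact.
Counts are real-valued expectations throughout; rounding to whole cases or
dollars happens only in the table writers, using round-half-away-from-zero.

Seven diseases are modelled with two evidence routes:

* **Group incidence** (LRTI, GII, AOM, NEC): annual incidences are
  available separately for formula-fed and exclusively breastfed infants,
  so cases follow directly from the feeding split. The headline "disease
  cases" count is the formula-fed group's cases, `N·(1−b)·p_FF` — this is
  the convention that reproduces the published provincial case counts that
  are reproducible at all (LRTI, NEC). Total-case and excess-case
  conventions are computable on request.
* **Odds ratio** (ALL, obesity, asthma): only an overall incidence *s* and
  a protective odds ratio *r* are published. The differential-incidence
  partition `x = s/(b·r + 1 − b)`, `x_exposed = x·r` allocates *s* across
  the groups so that `b·x·r + (1−b)·x = s` holds exactly; attributable
  cases are the unexposed excess `N·(1−b)·x·(1−r)` times the at-risk
  window. The partition treats the odds ratio as a risk ratio, valid for
  rare outcomes; the implementation emits a warning whenever `s > 0.1`
  (childhood obesity, at s = 0.131, triggers it).

### Cohorts

The reference population subtracts infant and neonatal mortality
additively (8.2 per 1,000 combined for the default registry): with 140,541
live births this gives 139,388.6 infants. The NEC chain deliberately does
*not* mortality-adjust: the early-preterm sub-cohort is
`births × preterm rate (0.081) × early-preterm fraction (0.143) ≈ 1,627.9`,
split at the 32.9% exclusive human-milk NICU-discharge rate. A composite
early-preterm share (1.16% of live births) that some sources print is
stored as an alternative override; the decomposition is the default
because it is what the downstream published counts follow.

### Scenarios

Each disease has a baseline rate and two counterfactuals, resolved from
the feeding-rate registry by disease-specific rate kinds: exclusive
breastfeeding at six months → discharge (64.9%) / initiation (92.1%) for
LRTI, GII, AOM, obesity and asthma; any breastfeeding at six months
(64.6%) → any breastfeeding at discharge (73.8%) / initiation for ALL; the
NICU human-milk rate (32.9%) → 64.9% / 92.1% for NEC. The NEC scenario-B
rate is nominally described in the source material as the 64.6%
any-breastfeeding-at-six-months rate, but the published savings figure
reproduces only with 64.9%; the registry defaults to the reproducing value
and the 64.6% kind is selectable. Savings are plain differences of burden
at the baseline and counterfactual rates; negative differences (rate
decreases, which the model does not cover) are clamped to zero with a
warning.

### Costing

Costs are linear in utilization quantities with no fixed-cost intercept.
Rules per disease:

* **inpatient–outpatient** (LRTI, GII):
  `cases·p_in·days·c_day + cases·p_out·visits·c_visit`. The unit-cost
  tables label inpatient costs "per stay", but only the per-day × length-
  of-stay reading reproduces the published GII total (to 0.002%), so
  per-day is the default with a `per_stay` switch.
* **episodes-per-case** (AOM): `cases·p_seek·episodes·c_episode` with 94%
  care-seeking and 2.2 episodes per year.
* **per-case** (NEC): unrounded cases × $60,326 per NICU-treated case. The
  31%/69% surgical/medical split is stored and reported but not separately
  costed, since the single per-case cost already reproduces the published
  dollars; a two-tier hook can be added through the schedule.
* **phase costs** (ALL): per-case cost is the care-seeking-weighted sum of
  the four published phase costs, `0.92·(c_prediag + c_initial) +
  0.85·c_continuing + 0.18·c_terminal ≈ $195,444` per case. The phase
  costs are already aggregated over the childhood horizon at source, so no
  additional discounting is applied by default.
* **annual excess** (obesity, asthma): obesity accrues $305.72 per
  child-year over 14 years as an annuity-due at the 3% discount rate
  (factor 11.6350). Asthma partitions cases by age-at-onset weights
  (0.399 / 0.429 / 0.172 for onset at 0–3, 4–7, 8–12 years), accrues
  $828.86 per year from the band midpoint (1.5, 5.5, 10 years — midpoints
  and the through-age-18-inclusive endpoint are this package's
  conventions, as the source states neither) and discounts each payment
  from birth.

Discounting uses start-of-year payments: `PV = Σ a_t/(1+ρ)^t`, default
ρ = 0.03. The stream is summed with compensated summation so a zero-rate
stream recovers the undiscounted sum exactly.

All packaged unit costs are stored as already expressed in 2020 US
dollars; `adjust_cost` (amount × inflation factor × exchange rate) exists
for users supplying raw source-currency inputs.

### Sensitivity analysis

One-way deterministic: one axis at a time, all else fixed. The unit-cost
axis sets every bounded cost component of a disease jointly to its low or
high published bound (ALL is skipped — its phase costs have no published
bounds, and the omission is logged). The odds-ratio axis applies to ALL,
obesity and asthma, using the confidence limits. Results are
parameter-anchored, not outcome-sorted: for a protective odds ratio the
low bound is more protective, so the "low" column carries the *larger*
savings; for unit costs low ≤ mean ≤ high. For per-case rules the low/high
results are exact scalar multiples of the mean (linearity).

## Synthetic data

`simulate_cohort` microsimulates the exact Bernoulli structure the closed
forms integrate over: feeding ~ Bernoulli(b), disease ~ Bernoulli of the
feeding-group incidence (group incidences taken directly, or from the
differential-incidence partition for odds-ratio diseases), care events ~
Bernoulli of the care-profile probabilities, costs per the costing rules.
Three pseudo-random streams (feeding, disease, care) are split from the
master seed with `SeedSequence.spawn`, so extending one component never
perturbs the others; identical seeds give bit-identical summaries. Means
and Monte-Carlo standard errors are estimated across replicates; the
default verification design is 20 replicates of 10,000 infants (200,000
simulated infants per disease), chosen so the replicate-based SE itself is
well estimated — with few replicates the 3-SE comparison is dominated by
noise in the SE estimate rather than in the mean. Because infants are
independent with the study's fixed rates, passing oracle checks confirms
the closed-form algebra and the costing rules; it says nothing about
clustering, time-varying feeding, comorbidity or cost heterogeneity in
real populations, none of which the simulator emulates.

`generate_parameter_set` draws random registry-valid parameter sets
(ordered low/point/high triples, proportions in [0,1], positive costs)
mirroring the packaged structure, for property-based fuzzing of the
validators and the null-effect/zero-savings invariants.

## Known non-reproductions

With the packaged inputs, these published figures are *not* recoverable
from the stated method, and the package intentionally computes the
method-faithful values instead:

* GII (27,883) and AOM (43,174) annual case counts (method gives 27,525
  and 32,852); likewise the averted counts 15,028 / 12,591 / 19,495.
* The LRTI annual cost $10,391,974 (rule-based value ≈ $7.77 M under
  either inpatient-unit interpretation).
* ALL (≈7), obesity (1,737) and asthma (2,492) attributable counts
  (method gives ≈3.1, 4,512 and 741 from the stated inputs).
* The obesity and asthma childhood totals, whose implied per-case
  multipliers exceed any combination of the published annual costs,
  horizon and 3% discounting.

The costing layer itself *does* reproduce the published dollars to better
than 0.1% when evaluated on the published case counts (GII $48.53 M, AOM
$8.72 M, NEC $4.61 M, GII discharge savings $21.91 M), which is how it is
validated; the case-count functions accept externally supplied counts for
exactly this purpose.

## Numerical conventions and limitations

* All arithmetic on unrounded floats; report-time rounding is
  half-away-from-zero for counts, whole dollars for money.
* Degenerate inputs fail fast with named validation errors (proportions
  outside [0,1], inverted low/point/high bounds, combined mortality ≥
  1,000/1,000, non-positive odds ratios or adjustment factors).
* The model is static: no time-varying rates or costs, no age structure
  beyond the asthma onset bands, no comorbidity interactions, no
  maternal-health, premature-death, caregiver-time or environmental costs.
* Disease ordering in outputs is fixed (LRTI, GII, AOM, NEC, ALL, obesity,
  asthma) for diffable CSVs; identical configuration and seed give
  byte-identical tables.
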
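# bfcost

A pediatric cost-of-illness model for suboptimal breastfeeding, built for
health economists and public-health analysts. Starting from a registry of
published provincial parameters — the 2019 Ontario live-birth cohort,
breastfeeding rates at initiation, hospital discharge and six months,
per-disease incidences or odds ratios, care-use profiles, and unit costs
with their published ranges — it computes breastfeeding-attributable cases,
hospitalizations, outpatient visits, and health-system costs for seven
childhood diseases (LRTI, GII, AOM, NEC, ALL, childhood obesity, asthma)
under counterfactual feeding-rate scenarios, and runs one-way deterministic
sensitivity analyses.

## The model

The reference population is the live-birth cohort adjusted for infant and
neonatal mortality, `N = births × (1 − (m_inf + m_neo)/1000)`, split into a
breastfed (exposed) and formula-fed (unexposed) group at the breastfeeding
rate *b*. Two evidence routes yield attributable cases:

* **Group incidences** (LRTI, GII, AOM, NEC): the headline count is the
  formula-fed group's cases, `N·(1−b)·p_FF`. NEC is restricted to the
  early-preterm (<32 weeks) NICU sub-cohort, split at the exclusive
  human-milk feeding rate at NICU discharge.
* **Differential incidence** (ALL, obesity, asthma): an overall incidence
  *s* is partitioned with `x = s/(b·r + 1 − b)` into group incidences *x*
  (unexposed) and *x·r* (exposed), *r* the odds ratio treated as a risk
  ratio; attributable cases are the unexposed group's excess,
  `N·(1−b)·(x − x·r)`, times the at-risk window in years.

Costs are linear in utilization: admissions × length-of-stay × per-day
cost plus outpatient episodes × visits × per-visit cost, or per-case /
per-episode schedules where that is how the unit costs are published.
Chronic childhood conditions accrue excess annual costs over a 14-year
horizon discounted at 3% per annum (annuity-due); asthma accrual starts at
the age-at-onset band midpoints and runs through age 18. Scenario savings
are differences between the burden at the current rate and at a
counterfactual rate (the discharge or initiation rate). A seeded
individual-level microsimulation of the same Bernoulli structure serves as
an independent Monte-Carlo oracle for every closed form.

## Worked example

```python
from bfcost import default_ontario_2019, run_all

params = default_ontario_2019()
run = run_all(params)

nec = run.result("NEC", "current")
saved = run.saving("NEC", "discharge")
print(f"NEC cases at the 32.9% NICU human-milk rate : {nec.cases:8.2f}")
print(f"Annual NEC treatment cost                   : ${nec.cost_usd:,.0f}")
print(f"Cases averted raising the rate to 64.9%     : {saved.cases_averted:8.2f}")
print(f"Annual savings                              : ${saved.cost_saved_usd:,.0f}")
```

prints

```
NEC cases at the 32.9% NICU human-milk rate :    76.46
Annual NEC treatment cost                   : $4,612,636
Cases averted raising the rate to 64.9%     :    36.46
Annual savings                              : $2,199,767
```

— of the roughly 1,628 early-preterm newborns, 1,092 leave the NICU without
exclusive human-milk feeding; 7% of those develop NEC (76.5 expected cases,
$60,326 per treated case). Raising the human-milk rate to the hospital
discharge rate would avert 36.5 cases and about $2.2 M per year. Counts
stay fractional inside the model (expected-value semantics) and are rounded
only when tables are written.

The same engine is available from the shell:

```sh
bfcost run --out out/                      # burden + savings CSV and manifest
bfcost sensitivity --axis unit-cost --out out/
bfcost simulate --n 100000 --seed 7 --disease LRTI --out out/
bfcost params --dump                       # the packaged parameter registry
```

Custom parameter sets are YAML/JSON documents validated against the JSON
Schema shipped at `bfcost/data/parameters.schema.json`; `--use-defaults`
fills unspecified keys from the packaged registry.

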
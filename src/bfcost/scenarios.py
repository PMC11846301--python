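"""Scenario engine: run every disease × feeding-rate scenario, difference
into savings, and one-way deterministic sensitivity analysis.

Scenario names are ``current`` (the observed baseline rate), ``discharge``
(raise the baseline to the hospital-discharge rate) and ``initiation``
(raise it to the initiation rate); the rate kind backing each scenario is
disease-specific and configured in the parameter registry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .cohort import Cohort, reference_population
from .costing import (BurdenResult, DiscountSpec, annual_treatment_cost,
                      care_episodes, childhood_cost)
from .diseases import (FeedingScenario, annual_cases_group_incidence,
                       attributable_cases_or, cases_averted,
                       nec_attributable_cases)
from .params import DISEASES, ParameterSet

__all__ = ["SavingsRow", "ScenarioRun", "SensitivityResult",
           "scenario_matrix", "disease_burden", "run_all",
           "one_way_sensitivity", "ANNUAL_DISEASES", "CHILDHOOD_DISEASES"]

log = logging.getLogger(__name__)

ANNUAL_DISEASES = ("LRTI", "GII", "AOM", "NEC")
CHILDHOOD_DISEASES = ("ALL", "obesity", "asthma")
SCENARIOS = ("current", "discharge", "initiation")


@dataclass(frozen=True)
class SavingsRow:
    """Differences (current − counterfactual) for one disease/scenario."""

    disease: str
    scenario: str
    cases_averted: float
    hospitalizations_averted: float
    outpatient_visits_averted: float
    cost_saved_usd: float


@dataclass
class ScenarioRun:
    """All burden results and savings for one parameter set."""

    parameter_set: ParameterSet
    scenario_matrix: dict[str, list[FeedingScenario]]
    results: list[BurdenResult] = field(default_factory=list)
    savings: list[SavingsRow] = field(default_factory=list)

    def result(self, disease: str, scenario: str) -> BurdenResult:
        for r in self.results:
            if r.disease == disease and r.scenario == scenario:
                return r
        raise KeyError((disease, scenario))

    def saving(self, disease: str, scenario: str) -> SavingsRow:
        for s in self.savings:
            if s.disease == disease and s.scenario == scenario:
                return s
        raise KeyError((disease, scenario))


@dataclass(frozen=True)
class SensitivityResult:
    """Cost savings with one parameter at its low, point and high value.

    ``low``/``high`` are anchored to the parameter's bounds, not sorted by
    outcome: for a protective odds ratio the low bound (more protective)
    yields the *larger* savings.
    """

    disease: str
    scenario: str
    varied_parameter: str
    low: float
    mean: float
    high: float


def scenario_matrix(params: ParameterSet
                    ) -> dict[str, list[FeedingScenario]]:
    """Baseline and counterfactual scenarios for every disease."""
    matrix: dict[str, list[FeedingScenario]] = {}
    for disease in DISEASES:
        spec = params.diseases[disease]
        base = params.rates.get(spec.baseline_rate_kind)
        scenarios = [FeedingScenario("current", base, base,
                                     spec.baseline_rate_kind)]
        for name, kind in spec.counterfactuals.items():
            scenarios.append(
                FeedingScenario(name, base, params.rates.get(kind), kind))
        matrix[disease] = scenarios
    return matrix


def disease_burden(params: ParameterSet, disease: str, bf_rate: float,
                   scenario: str = "current") -> BurdenResult:
    """Cases, care episodes and cost for one disease at one feeding rate."""
    spec = params.diseases[disease]
    care = params.care[disease]
    costs = params.costs[disease]
    discount = DiscountSpec(rate=params.discount_rate)

    if disease == "NEC":
        cases = nec_attributable_cases(
            params.cohort.live_births, params.cohort.preterm_rate,
            params.cohort.early_preterm_fraction, bf_rate, spec.group)
    else:
        cohort = reference_population(
            params.cohort.live_births,
            params.cohort.infant_mortality_per_1000,
            params.cohort.neonatal_mortality_per_1000)
        if spec.model == "group-incidence":
            cases = annual_cases_group_incidence(cohort, bf_rate, spec.group)
        else:
            cases = attributable_cases_or(cohort, bf_rate, spec.odds)

    hosp, outpatient = care_episodes(cases, care)
    if spec.horizon == "annual":
        cost = annual_treatment_cost(cases, care, costs)
    else:
        cost = childhood_cost(cases, costs, discount)
    return BurdenResult(disease=disease, scenario=scenario,
                        cases=cases.cases, hospitalizations=hosp,
                        outpatient_visits=outpatient, cost_usd=cost,
                        horizon=spec.horizon)


def run_all(params: ParameterSet) -> ScenarioRun:
    """Evaluate every disease at its baseline and counterfactual rates.

    Savings are straight differences of the burden at the baseline rate and
    at each counterfactual rate; a disease's baseline scenario always has
    zero savings.
    """
    matrix = scenario_matrix(params)
    run = ScenarioRun(parameter_set=params, scenario_matrix=matrix)
    for disease in DISEASES:
        by_scenario: dict[str, BurdenResult] = {}
        for scen in matrix[disease]:
            res = disease_burden(params, disease, scen.counterfactual_rate,
                                 scen.name)
            by_scenario[scen.name] = res
            run.results.append(res)
        current = by_scenario["current"]
        for scen in matrix[disease]:
            cf = by_scenario[scen.name]
            averted = cases_averted(
                _as_count(current, params, disease),
                _as_count(cf, params, disease))
            run.savings.append(SavingsRow(
                disease=disease, scenario=scen.name,
                cases_averted=averted.cases,
                hospitalizations_averted=max(
                    current.hospitalizations - cf.hospitalizations, 0.0),
                outpatient_visits_averted=max(
                    current.outpatient_visits - cf.outpatient_visits, 0.0),
                cost_saved_usd=max(current.cost_usd - cf.cost_usd, 0.0)))
    return run


def _as_count(result: BurdenResult, params: ParameterSet, disease: str):
    from .diseases import CaseCount
    convention = ("excess-cases"
                  if params.diseases[disease].model == "odds-ratio"
                  else "ff-group-cases")
    return CaseCount(result.cases, convention)


def totals(run: ScenarioRun, block: str, scenario: str
           ) -> tuple[float, float]:
    """(cases, cost) summed over a block ('annual' or 'childhood-14y')."""
    diseases = (ANNUAL_DISEASES if block == "annual" else CHILDHOOD_DISEASES)
    if scenario == "current":
        rows = [run.result(d, "current") for d in diseases]
        return (sum(r.cases for r in rows), sum(r.cost_usd for r in rows))
    rows = [run.saving(d, scenario) for d in diseases]
    return (sum(r.cases_averted for r in rows),
            sum(r.cost_saved_usd for r in rows))


def one_way_sensitivity(params: ParameterSet,
                        axis: str) -> list[SensitivityResult]:
    """One-way deterministic sensitivity of scenario cost savings.

    ``axis='unit-cost'`` sets every bounded unit cost of a disease to its
    low/high bound jointly; diseases without cost bounds are skipped with a
    log entry.  ``axis='odds-ratio'`` varies the odds ratio over its
    confidence interval and applies only to the odds-ratio diseases.
    """
    if axis not in ("unit-cost", "odds-ratio"):
        raise ValueError(f"axis must be 'unit-cost' or 'odds-ratio', "
                         f"got {axis!r}")
    results: list[SensitivityResult] = []
    for disease in DISEASES:
        variants = _parameter_variants(params, disease, axis)
        if variants is None:
            log.info("sensitivity axis %s skipped for %s (no bounds)",
                     axis, disease)
            continue
        low_params, high_params = variants
        runs = {tag: run_all(p) for tag, p in
                (("low", low_params), ("mean", params), ("high", high_params))}
        for scenario in SCENARIOS[1:]:
            results.append(SensitivityResult(
                disease=disease, scenario=scenario, varied_parameter=axis,
                low=runs["low"].saving(disease, scenario).cost_saved_usd,
                mean=runs["mean"].saving(disease, scenario).cost_saved_usd,
                high=runs["high"].saving(disease, scenario).cost_saved_usd))
    return results


def _parameter_variants(params: ParameterSet, disease: str, axis: str):
    """(low, high) deep-copies of the registry, or None to skip."""
    if axis == "odds-ratio":
        spec = params.diseases[disease]
        if spec.model != "odds-ratio":
            return None
        pv = spec.odds.odds_ratio
        if pv.low is None or pv.high is None:
            return None
        return (_with_or(params, disease, pv.low),
                _with_or(params, disease, pv.high))
    schedule = params.costs[disease]
    bounded = [name for name in ("inpatient_unit", "outpatient_unit",
                                 "per_case", "annual_excess")
               if (pv := getattr(schedule, name)) is not None
               and pv.low is not None and pv.high is not None]
    if not bounded:
        return None
    return (_with_costs(params, disease, bounded, "low"),
            _with_costs(params, disease, bounded, "high"))


def _with_or(params: ParameterSet, disease: str, value: float) -> ParameterSet:
    doc = params.model_dump()
    doc["diseases"][disease]["odds"]["odds_ratio"]["point"] = value
    return ParameterSet.model_validate(doc)


def _with_costs(params: ParameterSet, disease: str, fields: list[str],
                bound: str) -> ParameterSet:
    doc = params.model_dump()
    for name in fields:
        pv = doc["costs"][disease][name]
        pv["point"] = pv[bound]
    return ParameterSet.model_validate(doc)
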
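"""Individual-level microsimulation oracle and random-parameter generator.

The closed-form model is an expected-value calculation over independent
Bernoulli structure: each infant is breastfed with probability ``b``,
develops the disease with the feeding-group incidence, and accrues care
episodes and costs per the costing rules.  Simulating that structure
directly gives an independent Monte-Carlo check of every closed-form stage,
and a seeded generator of random-but-valid parameter sets supports
property-based testing of the registry validators.

Three independent pseudo-random streams (feeding, disease, care) are split
deterministically from the master seed, so adding draws to one component
never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .diseases import differential_incidence
from .params import (CareProfile, CostSchedule, GroupIncidenceDisease,
                     OddsRatioDisease, ParameterSet, ParameterValue,
                     default_ontario_2019)

__all__ = ["SimConfig", "SimSummary", "simulate_cohort",
           "generate_parameter_set"]

Disease = Union[GroupIncidenceDisease, OddsRatioDisease]


@dataclass(frozen=True)
class SimConfig:
    """One microsimulation experiment."""

    n_infants: int
    seed: int
    bf_rate: float
    disease: Disease
    care: CareProfile
    costs: CostSchedule
    replicates: int = 1

    def __post_init__(self) -> None:
        if self.n_infants < 1 or self.replicates < 1:
            raise ValueError("n_infants and replicates must be >= 1")
        if not 0.0 <= self.bf_rate <= 1.0:
            raise ValueError("bf_rate must be in [0,1]")


@dataclass(frozen=True)
class SimSummary:
    """Replicate means and Monte-Carlo standard errors."""

    mean_cases: float
    mean_hospitalizations: float
    mean_outpatient_visits: float
    mean_cost_usd: float
    se_cases: float
    se_hospitalizations: float
    se_outpatient_visits: float
    se_cost_usd: float
    n_infants: int
    replicates: int


def _group_incidences(disease: Disease, bf_rate: float) -> tuple[float, float]:
    """(incidence_ff, incidence_bf) for either disease parameterization."""
    if isinstance(disease, GroupIncidenceDisease):
        return disease.incidence_ff, disease.incidence_bf
    res = differential_incidence(disease.overall_incidence, bf_rate,
                                 disease.odds_ratio.point)
    return res.x, res.xr


def simulate_cohort(config: SimConfig) -> SimSummary:
    """Simulate independent infants and summarize the formula-fed burden.

    Per infant: feeding ~ Bernoulli(bf_rate); disease ~ Bernoulli of the
    feeding-group incidence; care events ~ Bernoulli of the care-profile
    proportions; costs follow the costing rule.  The reported case count is
    the formula-fed-group count, matching the closed-form headline
    convention.  Identical seeds give identical output.
    """
    feed_ss, disease_ss, care_ss = np.random.SeedSequence(
        config.seed).spawn(3)
    rng_feed = np.random.default_rng(feed_ss)
    rng_disease = np.random.default_rng(disease_ss)
    rng_care = np.random.default_rng(care_ss)

    inc_ff, inc_bf = _group_incidences(config.disease, config.bf_rate)
    n = config.n_infants
    care, costs = config.care, config.costs

    stats = np.zeros((config.replicates, 4))
    for rep in range(config.replicates):
        bf = rng_feed.random(n) < config.bf_rate
        p = np.where(bf, inc_bf, inc_ff)
        ill = rng_disease.random(n) < p
        ff_cases = int(np.count_nonzero(ill & ~bf))

        hosp = visits = cost = 0.0
        if ff_cases:
            if care.episodes_per_year > 0:  # care-seeking episode model
                seeks = rng_care.random(ff_cases) < care.p_care_seeking
                n_seek = int(np.count_nonzero(seeks))
                visits = n_seek * care.episodes_per_year
                if costs.rule == "episodes-per-case":
                    cost = visits * costs.per_case.point
            else:
                admitted = rng_care.random(ff_cases) < care.p_inpatient
                outpat = rng_care.random(ff_cases) < care.p_outpatient
                hosp = float(np.count_nonzero(admitted))
                visits = float(np.count_nonzero(outpat)) * care.outpatient_visits
                if costs.rule == "inpatient-outpatient":
                    days = 1.0 if costs.per_stay else care.inpatient_days
                    cost = (hosp * days * costs.inpatient_unit.point
                            + visits * costs.outpatient_unit.point)
            if costs.rule == "per-case":
                cost = ff_cases * costs.per_case.point
        stats[rep] = (ff_cases, hosp, visits, cost)

    means = stats.mean(axis=0)
    if config.replicates > 1:
        ses = stats.std(axis=0, ddof=1) / np.sqrt(config.replicates)
    else:
        ses = np.full(4, np.nan)
    return SimSummary(
        mean_cases=means[0], mean_hospitalizations=means[1],
        mean_outpatient_visits=means[2], mean_cost_usd=means[3],
        se_cases=ses[0], se_hospitalizations=ses[1],
        se_outpatient_visits=ses[2], se_cost_usd=ses[3],
        n_infants=n, replicates=config.replicates)


def generate_parameter_set(seed: int,
                           ranges: Optional[dict] = None) -> ParameterSet:
    """A random but registry-valid parameter set for property testing.

    The structure (seven diseases, model kinds, costing rules) mirrors the
    packaged defaults; every numeric value is resampled.  Deterministic
    under ``seed``.  ``ranges`` may override the sampling intervals for
    ``incidence`` (group incidences), ``odds_ratio`` and ``unit_cost``.
    """
    rng = np.random.default_rng(seed)
    spans = {"incidence": (0.005, 0.5), "odds_ratio": (0.3, 1.5),
             "unit_cost": (10.0, 100_000.0)}
    if ranges:
        spans.update(ranges)

    def prop() -> float:
        return float(rng.uniform(0.0, 1.0))

    def bounded_cost() -> ParameterValue:
        lo, hi = spans["unit_cost"]
        a, b, c = np.sort(rng.uniform(lo, hi, 3))
        return ParameterValue(point=float(b), low=float(a), high=float(c),
                              units="USD", source="synthetic")

    def bounded_or() -> ParameterValue:
        lo, hi = spans["odds_ratio"]
        a, b, c = np.sort(rng.uniform(lo, hi, 3))
        return ParameterValue(point=float(b), low=float(a), high=float(c),
                              units="odds-ratio", source="synthetic")

    doc = default_ontario_2019().model_dump()
    doc["cohort"].update(
        live_births=float(rng.integers(1_000, 1_000_000)),
        infant_mortality_per_1000=float(rng.uniform(0, 20)),
        neonatal_mortality_per_1000=float(rng.uniform(0, 20)),
        preterm_rate=float(rng.uniform(0, 0.3)),
        early_preterm_fraction=float(rng.uniform(0, 0.5)))
    for key in ("ebf_6mo", "ebf_discharge", "initiation", "anybf_discharge",
                "anybf_6mo", "ebm_nicu_discharge"):
        doc["rates"][key] = prop()

    lo_inc, hi_inc = spans["incidence"]
    for name, spec in doc["diseases"].items():
        if spec["model"] == "group-incidence":
            a, b = np.sort(rng.uniform(lo_inc, hi_inc, 2))
            spec["group"]["incidence_ff"] = float(b)
            spec["group"]["incidence_bf"] = float(a)
        else:
            spec["odds"]["overall_incidence"] = float(
                rng.uniform(lo_inc, min(hi_inc, 0.3)))
            spec["odds"]["odds_ratio"] = bounded_or().model_dump()
            spec["odds"]["exposure_years"] = float(rng.uniform(1, 10))

    for name, schedule in doc["costs"].items():
        for field in ("inpatient_unit", "outpatient_unit", "per_case",
                      "annual_excess"):
            if schedule.get(field) is not None:
                schedule[field] = bounded_cost().model_dump()
        if schedule.get("phase_costs") is not None:
            schedule["phase_costs"] = {
                phase: float(rng.uniform(1_000, 400_000))
                for phase in schedule["phase_costs"]}
            schedule["phase_uptake"] = {
                phase: prop() for phase in schedule["phase_uptake"]}

    for name, care in doc["care"].items():
        if care["episodes_per_year"] > 0:
            care["p_care_seeking"] = prop()
            care["episodes_per_year"] = float(rng.uniform(0.5, 5))
        else:
            care["p_inpatient"] = prop()
            care["p_outpatient"] = prop()
            care["inpatient_days"] = float(rng.uniform(0.5, 40))
            care["outpatient_visits"] = float(rng.uniform(0.5, 5))

    doc["discount_rate"] = float(rng.uniform(0, 0.1))
    return ParameterSet.model_validate(doc)
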
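"""Care episodes, annual treatment costs, and discounted childhood costs.

The cost model is linear: utilization quantities times unit costs, with no
fixed-cost intercept.  Annual diseases (LRTI, GII, AOM, NEC) are costed for
one year of treatment; chronic childhood conditions (ALL, obesity, asthma)
accumulate costs over a 14-year childhood horizon, discounted to present
value at 3% per annum by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal

from .diseases import CaseCount
from .params import CareProfile, CostSchedule

__all__ = [
    "BurdenResult", "DiscountSpec", "care_episodes", "annual_treatment_cost",
    "discount_stream", "annuity_due", "childhood_cost_all",
    "childhood_cost_annual_excess", "childhood_cost",
]


@dataclass(frozen=True)
class DiscountSpec:
    """Annual discounting with payments at the start of each year."""

    rate: float = 0.03
    timing: Literal["start-of-year"] = "start-of-year"
    base_year_offset: int = 0

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("discount rate must be non-negative")


@dataclass(frozen=True)
class BurdenResult:
    """Cases, care episodes and cost for one disease under one scenario."""

    disease: str
    scenario: str
    cases: float
    hospitalizations: float
    outpatient_visits: float
    cost_usd: float
    horizon: Literal["annual", "childhood-14y"] = "annual"

    def __post_init__(self) -> None:
        for name in ("cases", "hospitalizations", "outpatient_visits",
                     "cost_usd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _n(cases: CaseCount | float) -> float:
    return cases.cases if isinstance(cases, CaseCount) else float(cases)


def care_episodes(cases: CaseCount | float,
                  profile: CareProfile) -> tuple[float, float]:
    """(hospitalizations, outpatient visit count) for a case count.

    Hospitalizations are admissions (``cases × p_inpatient``).  Outpatient
    volume is ``cases × p_outpatient × visits-per-episode``; for diseases
    modelled through care-seeking episodes (AOM) it is
    ``cases × p_care_seeking × episodes-per-year``.
    """
    n = _n(cases)
    hospitalizations = n * profile.p_inpatient
    if profile.episodes_per_year > 0:
        outpatient = n * profile.p_care_seeking * profile.episodes_per_year
    else:
        outpatient = n * profile.p_outpatient * profile.outpatient_visits
    return hospitalizations, outpatient


def annual_treatment_cost(cases: CaseCount | float, profile: CareProfile,
                          costs: CostSchedule,
                          rule: str | None = None) -> float:
    """One year of treatment cost for an annual disease.

    Rules
    -----
    ``inpatient-outpatient``
        admissions × length-of-stay × per-day cost, plus outpatient
        episodes × visits × per-visit cost.  With ``costs.per_stay`` the
        inpatient unit is charged once per admission instead of per day.
    ``episodes-per-case``
        care-seeking cases × episodes per year × cost per episode.
    ``per-case``
        unrounded cases × cost per treated case.
    """
    n = _n(cases)
    rule = rule or costs.rule
    if rule == "inpatient-outpatient":
        days = 1.0 if costs.per_stay else profile.inpatient_days
        inpatient = n * profile.p_inpatient * days * costs.inpatient_unit.point
        outpatient = (n * profile.p_outpatient * profile.outpatient_visits
                      * costs.outpatient_unit.point)
        return inpatient + outpatient
    if rule == "episodes-per-case":
        return (n * profile.p_care_seeking * profile.episodes_per_year
                * costs.per_case.point)
    if rule == "per-case":
        return n * costs.per_case.point
    raise ValueError(f"unknown costing rule {rule!r}")


def discount_stream(payments: Iterable[tuple[float, float]],
                    spec: DiscountSpec = DiscountSpec()) -> float:
    """Present value of (year-offset, amount) payments: Σ a/(1+r)^t."""
    terms = []
    for offset, amount in payments:
        if amount < 0:
            raise ValueError("payment amounts must be non-negative")
        terms.append(
            amount / (1.0 + spec.rate) ** (offset - spec.base_year_offset))
    return math.fsum(terms)


def annuity_due(years: int, rate: float) -> float:
    """PV of a unit payment at the start of each of ``years`` years."""
    if years < 0:
        raise ValueError("years must be non-negative")
    if rate == 0:
        return float(years)
    return (1.0 - (1.0 + rate) ** -years) / rate * (1.0 + rate)


def childhood_cost_all(cases: CaseCount | float,
                       schedule: CostSchedule) -> float:
    """Childhood (14-year) treatment cost for acute lymphoblastic leukemia.

    Per-case cost is the uptake-weighted sum of phase costs (pre-diagnosis,
    initial/first-year, continuing-care, terminal).  The published phase
    costs already aggregate each phase over the childhood horizon, so no
    further discounting is applied.
    """
    per_case = sum(schedule.phase_uptake[phase] * cost
                   for phase, cost in schedule.phase_costs.items())
    return _n(cases) * per_case


def childhood_cost_annual_excess(cases: CaseCount | float,
                                 annual_excess: float,
                                 years: float = 14,
                                 spec: DiscountSpec = DiscountSpec(),
                                 onset_bands=None) -> float:
    """Discounted excess healthcare cost for a chronic childhood condition.

    Without onset bands (obesity): every case accrues ``annual_excess`` for
    ``years`` years starting at disease onset, discounted as an annuity-due.

    With onset bands (asthma): cases are partitioned by age-at-onset weights;
    each band accrues ``annual_excess`` yearly from its midpoint onset age
    through age 18 inclusive, discounted from birth.
    """
    n = _n(cases)
    if annual_excess < 0 or years < 0:
        raise ValueError("annual_excess and years must be non-negative")
    if onset_bands is None:
        factor = annuity_due(int(round(years)), spec.rate)
        return n * annual_excess * factor
    per_case = 0.0
    for band in onset_bands:
        ages = _accrual_ages(band.midpoint_age, last_age=18.0)
        per_case += band.weight * discount_stream(
            ((age, annual_excess) for age in ages), spec)
    return n * per_case


def _accrual_ages(onset: float, last_age: float) -> list[float]:
    ages, age = [], onset
    while age <= last_age + 1e-9:
        ages.append(age)
        age += 1.0
    return ages


def childhood_cost(cases: CaseCount | float, schedule: CostSchedule,
                   spec: DiscountSpec = DiscountSpec()) -> float:
    """Dispatch childhood costing by the schedule's rule."""
    if schedule.rule == "phase-costs":
        return childhood_cost_all(cases, schedule)
    if schedule.rule == "annual-excess":
        return childhood_cost_annual_excess(
            cases, schedule.annual_excess.point, schedule.years, spec,
            schedule.onset_bands)
    raise ValueError(f"not a childhood costing rule: {schedule.rule!r}")
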
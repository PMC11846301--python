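"""Attributable-case computation.

Two routes, matching how the evidence is published:

* **group incidence** (LRTI, GII, AOM, NEC): per-group annual incidences
  for formula-fed and exclusively breastfed infants are applied directly.
  The headline "disease cases" convention is the formula-fed-group count —
  cases arising in the unexposed group.

* **odds ratio** (ALL, obesity, asthma): an overall incidence *s* is
  partitioned into group incidences with the differential-incidence
  equation ``x = s/(b·r + 1 − b)`` (x in the non-breastfed group, x·r in
  the breastfed group, b the breastfeeding rate, r the odds ratio treated
  as a risk ratio).  Attributable cases are the excess in the unexposed
  group, ``size × (1−b) × (x − x·r) × exposure_years``.

Scenario savings are differences of case counts at the baseline and a
counterfactual feeding rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

from .cohort import Cohort, early_preterm_population, feeding_split
from .params import GroupIncidenceDisease, OddsRatioDisease

__all__ = [
    "FeedingScenario", "DifferentialIncidenceResult", "CaseCount",
    "ModelWarning", "differential_incidence", "annual_cases_group_incidence",
    "nec_attributable_cases", "attributable_cases_or", "cases_averted",
]

#: Overall incidence above which the odds-ratio ≈ risk-ratio approximation
#: becomes doubtful (the rare-disease assumption).
RARE_DISEASE_THRESHOLD = 0.1

Convention = Literal["ff-group-cases", "excess-cases", "total-cases"]


class ModelWarning(UserWarning):
    """Non-fatal modelling caveat (clamped negatives, doubtful approximations)."""


@dataclass(frozen=True)
class FeedingScenario:
    """One counterfactual: raise ``baseline_rate`` to ``counterfactual_rate``."""

    name: str
    baseline_rate: float
    counterfactual_rate: float
    rate_kind: str = ""

    def __post_init__(self) -> None:
        for r in (self.baseline_rate, self.counterfactual_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rates must be in [0,1], got {r}")


@dataclass(frozen=True)
class DifferentialIncidenceResult:
    """Group incidences from the differential-incidence partition."""

    x: float   #: incidence in the non-breastfed group
    xr: float  #: incidence in the breastfed group (= x·r)


@dataclass(frozen=True)
class CaseCount:
    """A non-negative expected case count with its counting convention."""

    cases: float
    convention: Convention = "ff-group-cases"

    def __post_init__(self) -> None:
        if self.cases < 0:
            raise ValueError("case counts must be non-negative")


def differential_incidence(s: float, b: float, r: float
                           ) -> DifferentialIncidenceResult:
    """Partition overall incidence ``s`` into group incidences.

    ``x = s/(b·r + 1 − b)``; the recombination identity
    ``b·x·r + (1−b)·x = s`` holds to machine precision.

    Emits a :class:`ModelWarning` when ``s`` exceeds 0.1, where treating the
    odds ratio as a risk ratio is no longer a good approximation.
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"overall incidence must be in [0,1], got {s}")
    if not 0.0 <= b <= 1.0:
        raise ValueError(f"breastfeeding rate must be in [0,1], got {b}")
    if r <= 0:
        raise ValueError(f"odds ratio must be positive, got {r}")
    denom = b * r + 1.0 - b
    if denom <= 0:
        raise ValueError("degenerate partition: b·r + 1 − b must be positive")
    if s > RARE_DISEASE_THRESHOLD:
        warnings.warn(
            f"overall incidence {s:.3f} > {RARE_DISEASE_THRESHOLD}: odds "
            "ratio may not approximate the risk ratio",
            ModelWarning, stacklevel=2)
    x = s / denom
    return DifferentialIncidenceResult(x=x, xr=x * r)


def annual_cases_group_incidence(
        cohort: Cohort, bf_rate: float, disease: GroupIncidenceDisease,
        convention: Convention = "ff-group-cases") -> CaseCount:
    """Annual cases for a group-incidence disease.

    The default headline convention counts formula-fed-group cases,
    ``size × (1−b) × incidence_ff``; ``total-cases`` adds the breastfed
    group and ``excess-cases`` is the difference attributable to not
    breastfeeding.
    """
    if not 0.0 <= bf_rate <= 1.0:
        raise ValueError(f"bf_rate must be in [0,1], got {bf_rate}")
    split = feeding_split(cohort, bf_rate)
    ff_cases = split.ff * disease.incidence_ff
    bf_cases = split.bf * disease.incidence_bf
    if convention == "ff-group-cases":
        cases = ff_cases
    elif convention == "total-cases":
        cases = ff_cases + bf_cases
    elif convention == "excess-cases":
        cases = split.ff * (disease.incidence_ff - disease.incidence_bf)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return CaseCount(max(cases, 0.0), convention)


def nec_attributable_cases(live_births: float, preterm_rate: float,
                           early_fraction: float, ebm_rate: float,
                           disease: GroupIncidenceDisease) -> CaseCount:
    """NEC cases among formula-fed early-preterm NICU infants.

    Chain: early-preterm sub-cohort → feeding split at the exclusive
    human-milk NICU-discharge rate → formula-fed group × incidence.  The
    unrounded value is carried into costing.
    """
    sub = early_preterm_population(live_births, preterm_rate, early_fraction)
    return annual_cases_group_incidence(sub, ebm_rate, disease)


def attributable_cases_or(cohort: Cohort, bf_rate: float,
                          disease: OddsRatioDisease,
                          exposure_years: float | None = None) -> CaseCount:
    """Excess cases in the unexposed group via the odds-ratio route.

    ``exposure_years`` defaults to the disease's configured risk window
    (1 for prevalence-based overall incidence; the length of the at-risk
    age range for person-year incidences).
    """
    years = disease.exposure_years if exposure_years is None else exposure_years
    if years < 0:
        raise ValueError("exposure_years must be non-negative")
    res = differential_incidence(disease.overall_incidence, bf_rate,
                                 disease.odds_ratio.point)
    excess = cohort.size * (1.0 - bf_rate) * (res.x - res.xr) * years
    if excess < 0:  # anti-protective odds ratio (r > 1)
        warnings.warn("odds ratio > 1: negative excess clamped to zero",
                      ModelWarning, stacklevel=2)
        excess = 0.0
    return CaseCount(excess, "excess-cases")


def cases_averted(current: CaseCount, counterfactual: CaseCount) -> CaseCount:
    """Cases prevented by the counterfactual: ``current − counterfactual``.

    Negative differences (a counterfactual that lowers the breastfeeding
    rate) are clamped to zero with a warning; rate decreases are outside
    the model.
    """
    if current.convention != counterfactual.convention:
        raise ValueError(
            f"convention mismatch: {current.convention!r} vs "
            f"{counterfactual.convention!r}")
    diff = current.cases - counterfactual.cases
    if diff < 0:
        warnings.warn("counterfactual exceeds current cases; averted count "
                      "clamped to zero", ModelWarning, stacklevel=2)
        diff = 0.0
    return CaseCount(diff, current.convention)
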
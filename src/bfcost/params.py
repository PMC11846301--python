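"""Typed parameter registry for the Ontario pediatric cost-of-illness model.

Every quantity the model consumes — the 2019 live-birth cohort, the six
provincial feeding rates, per-disease incidences or odds ratios, care-use
profiles, and unit costs with their published low/high bounds — lives in a
single validated :class:`ParameterSet`.  The packaged defaults are returned
by :func:`default_ontario_2019`; user-supplied YAML/JSON configurations are
loaded with :func:`load_parameters` and validated against the same schema.

Costs are stored in 2020 US dollars, the currency the published unit costs
are expressed in.  :func:`adjust_cost` exists for users supplying raw
Canadian-dollar inputs from other years.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "ParameterValue",
    "CohortParams",
    "FeedingRates",
    "CurrencyAdjustment",
    "GroupIncidenceDisease",
    "OddsRatioDisease",
    "DiseaseSpec",
    "CareProfile",
    "OnsetBand",
    "CostSchedule",
    "ParameterSet",
    "RateKind",
    "DISEASES",
    "default_ontario_2019",
    "load_parameters",
    "dump_parameters",
    "adjust_cost",
    "parameter_schema",
]

#: Canonical disease ordering used in every report.
DISEASES = ("LRTI", "GII", "AOM", "NEC", "ALL", "obesity", "asthma")

RateKind = Literal[
    "ebf_6mo",
    "ebf_discharge",
    "initiation",
    "anybf_discharge",
    "anybf_6mo",
    "ebm_nicu_discharge",
]

Units = Literal[
    "proportion", "USD", "days", "visits", "episodes", "per-1000",
    "per-100k-person-years", "count", "odds-ratio", "years",
]

_PROPORTION_UNITS = {"proportion"}


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class ParameterValue(_Model):
    """A point estimate with optional published low/high bounds.

    ``low``/``high`` come from the published ranges (e.g. minimum/maximum
    unit costs, odds-ratio confidence limits) and drive the one-way
    sensitivity analysis.  ``source`` is a free-text provenance label; it is
    stored verbatim and never interpreted.
    """

    point: float
    low: Optional[float] = None
    high: Optional[float] = None
    units: Units = "USD"
    source: str = ""

    @model_validator(mode="after")
    def _check_bounds(self) -> "ParameterValue":
        vals = [v for v in (self.low, self.point, self.high) if v is not None]
        if any(v < 0 for v in vals):
            raise ValueError(f"negative value in {vals} ({self.units})")
        if self.units in _PROPORTION_UNITS and any(v > 1 for v in vals):
            raise ValueError(f"proportion outside [0,1]: {vals}")
        if self.low is not None and self.low > self.point:
            raise ValueError(f"low {self.low} > point {self.point}")
        if self.high is not None and self.high < self.point:
            raise ValueError(f"high {self.high} < point {self.point}")
        return self

    def with_point(self, value: float) -> "ParameterValue":
        """Copy with ``point`` replaced and bounds widened to admit it."""
        low = None if self.low is None else min(self.low, value)
        high = None if self.high is None else max(self.high, value)
        return self.model_copy(update={"point": value, "low": low, "high": high})


Proportion = Field(ge=0.0, le=1.0)


class CohortParams(_Model):
    """Birth-cohort size and the vital rates used to adjust it."""

    live_births: float = Field(ge=0)
    infant_mortality_per_1000: float = Field(ge=0)
    neonatal_mortality_per_1000: float = Field(ge=0)
    preterm_rate: float = Proportion
    early_preterm_fraction: float = Proportion
    #: Alternative composite early-preterm share of all live births
    #: (some sources print the product directly); not used by default.
    early_preterm_composite: Optional[float] = Field(default=None, ge=0, le=1)
    source: str = ""


class FeedingRates(_Model):
    """Provincial breastfeeding rates at the model's exposure time points."""

    ebf_6mo: float = Proportion
    ebf_discharge: float = Proportion
    initiation: float = Proportion
    anybf_discharge: float = Proportion
    anybf_6mo: float = Proportion
    ebm_nicu_discharge: float = Proportion
    source: str = ""

    def get(self, kind: RateKind) -> float:
        return getattr(self, kind)


class CurrencyAdjustment(_Model):
    """Multiplicative inflation + CAD→USD exchange adjustment.

    The packaged unit costs are already in target-year USD, so the default
    adjustment is the identity; supply real factors when feeding the model
    raw source-currency costs.
    """

    inflation_factor: float = Field(default=1.0, gt=0)
    fx_rate: float = Field(default=1.0, gt=0)
    target_year: int = 2020


class GroupIncidenceDisease(_Model):
    """Per-group annual incidence: formula-fed vs exclusively breastfed."""

    incidence_ff: float = Proportion
    incidence_bf: float = Proportion
    source: str = ""


class OddsRatioDisease(_Model):
    """Overall incidence plus a protective odds ratio.

    The differential-incidence partition splits ``overall_incidence`` into
    group incidences given the exposure prevalence; ``exposure_years``
    converts a per-person-year incidence into cumulative cases over the
    at-risk window (1 for prevalence-based inputs).
    """

    overall_incidence: float = Proportion
    odds_ratio: ParameterValue
    exposure_years: float = Field(default=1.0, gt=0)
    source: str = ""

    @model_validator(mode="after")
    def _check_or(self) -> "OddsRatioDisease":
        if self.odds_ratio.point <= 0:
            raise ValueError("odds ratio must be positive")
        return self


class DiseaseSpec(_Model):
    """Model choice and scenario wiring for one disease."""

    model: Literal["group-incidence", "odds-ratio"]
    horizon: Literal["annual", "childhood-14y"]
    population: Literal["full-cohort", "early-preterm"] = "full-cohort"
    baseline_rate_kind: RateKind
    #: scenario name -> feeding-rate kind of the counterfactual rate
    counterfactuals: dict[str, RateKind]
    group: Optional[GroupIncidenceDisease] = None
    odds: Optional[OddsRatioDisease] = None

    @model_validator(mode="after")
    def _check_model(self) -> "DiseaseSpec":
        if self.model == "group-incidence" and self.group is None:
            raise ValueError("group-incidence disease requires `group`")
        if self.model == "odds-ratio" and self.odds is None:
            raise ValueError("odds-ratio disease requires `odds`")
        return self


class CareProfile(_Model):
    """Probabilities and intensities of care per case."""

    p_inpatient: float = Field(default=0.0, ge=0, le=1)
    inpatient_days: float = Field(default=0.0, ge=0)
    p_outpatient: float = Field(default=0.0, ge=0, le=1)
    outpatient_visits: float = Field(default=0.0, ge=0)
    p_care_seeking: float = Field(default=0.0, ge=0, le=1)
    episodes_per_year: float = Field(default=0.0, ge=0)
    #: share of treated cases needing surgery (stored, reported, not
    #: separately costed: the per-case NICU cost already covers both tiers)
    surgical_fraction: Optional[float] = Field(default=None, ge=0, le=1)
    source: str = ""


class OnsetBand(_Model):
    """One age-at-onset band for chronic-disease cost accrual."""

    weight: float = Proportion
    midpoint_age: float = Field(ge=0)


class CostSchedule(_Model):
    """Unit costs and the costing rule that combines them with care use."""

    rule: Literal[
        "inpatient-outpatient", "episodes-per-case", "per-case",
        "phase-costs", "annual-excess",
    ]
    inpatient_unit: Optional[ParameterValue] = None  # USD per inpatient day
    outpatient_unit: Optional[ParameterValue] = None  # USD per visit
    per_case: Optional[ParameterValue] = None
    phase_costs: Optional[dict[str, float]] = None
    phase_uptake: Optional[dict[str, float]] = None
    annual_excess: Optional[ParameterValue] = None  # USD per child-year
    years: float = Field(default=14.0, ge=0)
    onset_bands: Optional[list[OnsetBand]] = None
    #: interpret inpatient_unit as per-stay instead of per-day
    per_stay: bool = False

    @model_validator(mode="after")
    def _check_rule(self) -> "CostSchedule":
        need = {
            "inpatient-outpatient": ("inpatient_unit", "outpatient_unit"),
            "episodes-per-case": ("per_case",),
            "per-case": ("per_case",),
            "phase-costs": ("phase_costs", "phase_uptake"),
            "annual-excess": ("annual_excess",),
        }[self.rule]
        for field in need:
            if getattr(self, field) is None:
                raise ValueError(f"rule {self.rule!r} requires {field}")
        if self.phase_costs is not None and self.phase_uptake is not None:
            missing = set(self.phase_costs) - set(self.phase_uptake)
            if missing:
                raise ValueError(f"phase_uptake missing phases {missing}")
        return self


class ParameterSet(_Model):
    """The full model registry: cohort, rates, diseases, care, costs."""

    cohort: CohortParams
    rates: FeedingRates
    diseases: dict[str, DiseaseSpec]
    care: dict[str, CareProfile]
    costs: dict[str, CostSchedule]
    discount_rate: float = Field(default=0.03, ge=0)
    currency: CurrencyAdjustment = CurrencyAdjustment()

    @model_validator(mode="after")
    def _check_diseases(self) -> "ParameterSet":
        for registry, label in ((self.diseases, "diseases"),
                                (self.care, "care"),
                                (self.costs, "costs")):
            missing = set(DISEASES) - set(registry)
            if missing:
                raise ValueError(f"{label} registry missing {sorted(missing)}")
        return self

    def baseline_rate(self, disease: str) -> float:
        return self.rates.get(self.diseases[disease].baseline_rate_kind)

    def counterfactual_rate(self, disease: str, scenario: str) -> float:
        return self.rates.get(self.diseases[disease].counterfactuals[scenario])


def default_ontario_2019() -> ParameterSet:
    """The packaged 2019 Ontario parameter registry.

    Point estimates and low/high bounds are the published provincial inputs:
    Statistics Canada vital statistics, Public Health Agency of Canada and
    Baby-Friendly Initiative Ontario feeding rates, Ontario Case Costing
    Initiative unit costs, and meta-analytic effect sizes from the
    literature.  All money is in 2020 US dollars.
    """
    usd = lambda p, lo=None, hi=None, src="": ParameterValue(  # noqa: E731
        point=p, low=lo, high=hi, units="USD", source=src)

    cohort = CohortParams(
        live_births=140_541,
        infant_mortality_per_1000=4.6,
        neonatal_mortality_per_1000=3.6,
        preterm_rate=0.081,
        early_preterm_fraction=0.143,
        early_preterm_composite=0.0116,
        source="Statistics Canada 2019 vital statistics; CIHI preterm rates",
    )
    rates = FeedingRates(
        ebf_6mo=0.363,
        ebf_discharge=0.649,
        initiation=0.921,
        anybf_discharge=0.738,
        anybf_6mo=0.646,
        ebm_nicu_discharge=0.329,
        source="PHAC 2022 (CCHS 2017-18); BFI Ontario annual report 2019; "
               "Canadian Neonatal Network",
    )

    ebf_scenarios: dict[str, RateKind] = {
        "discharge": "ebf_discharge", "initiation": "initiation"}

    diseases: dict[str, DiseaseSpec] = {
        "LRTI": DiseaseSpec(
            model="group-incidence", horizon="annual",
            baseline_rate_kind="ebf_6mo", counterfactuals=ebf_scenarios,
            group=GroupIncidenceDisease(
                incidence_ff=0.37, incidence_bf=0.25,
                source="Quesada et al. 2020"),
        ),
        "GII": DiseaseSpec(
            model="group-incidence", horizon="annual",
            baseline_rate_kind="ebf_6mo", counterfactuals=ebf_scenarios,
            group=GroupIncidenceDisease(
                incidence_ff=0.31, incidence_bf=0.14,
                source="Quesada et al. 2020"),
        ),
        "AOM": DiseaseSpec(
            model="group-incidence", horizon="annual",
            baseline_rate_kind="ebf_6mo", counterfactuals=ebf_scenarios,
            group=GroupIncidenceDisease(
                incidence_ff=0.37, incidence_bf=0.25,
                source="Quesada et al. 2020"),
        ),
        # NEC: early-preterm (<32 w) sub-cohort, exposure is exclusive
        # human-milk feeding at NICU discharge.  The scenario-B
        # counterfactual defaults to the 64.9% discharge rate, the value
        # that reproduces the published savings; the nominally described
        # 64.6% any-BF-at-6-months alternative is selectable by overriding
        # counterfactuals["discharge"] to "anybf_6mo".
        "NEC": DiseaseSpec(
            model="group-incidence", horizon="annual",
            population="early-preterm",
            baseline_rate_kind="ebm_nicu_discharge",
            counterfactuals={"discharge": "ebf_discharge",
                             "initiation": "initiation"},
            group=GroupIncidenceDisease(
                incidence_ff=0.07, incidence_bf=0.01,
                source="Quesada et al. 2020"),
        ),
        # ALL: incidence 7.0 per 100k person-years among 0-4 year olds;
        # exposure is any breastfeeding >= 6 months, 5-year risk window.
        "ALL": DiseaseSpec(
            model="odds-ratio", horizon="childhood-14y",
            baseline_rate_kind="anybf_6mo",
            counterfactuals={"discharge": "anybf_discharge",
                             "initiation": "initiation"},
            odds=OddsRatioDisease(
                overall_incidence=7.0 / 100_000,
                odds_ratio=ParameterValue(
                    point=0.84, low=0.75, high=0.94, units="odds-ratio",
                    source="Amitay & Keinan-Boker 2015"),
                exposure_years=5.0,
                source="Statistics Canada cancer incidence"),
        ),
        "obesity": DiseaseSpec(
            model="odds-ratio", horizon="childhood-14y",
            baseline_rate_kind="ebf_6mo", counterfactuals=ebf_scenarios,
            odds=OddsRatioDisease(
                overall_incidence=0.131,
                odds_ratio=ParameterValue(
                    point=0.66, low=0.50, high=0.88, units="odds-ratio",
                    source="Ma et al. 2020"),
                exposure_years=1.0,
                source="Rao et al. 2016 (prevalence, ages 1-19)"),
        ),
        "asthma": DiseaseSpec(
            model="odds-ratio", horizon="childhood-14y",
            baseline_rate_kind="ebf_6mo", counterfactuals=ebf_scenarios,
            odds=OddsRatioDisease(
                overall_incidence=24.8 / 1000,
                odds_ratio=ParameterValue(
                    point=0.70, low=0.53, high=0.92, units="odds-ratio",
                    source="Xue et al. 2021"),
                exposure_years=1.0,
                source="Radhakrishnan et al. 2021 (per 1000 person-years, "
                       "ages 0-10)"),
        ),
    }

    care: dict[str, CareProfile] = {
        "LRTI": CareProfile(p_inpatient=0.06, inpatient_days=3.0,
                            p_outpatient=0.23, outpatient_visits=1.9,
                            source="Renfrew et al. 2012; CIHI; OCCI"),
        "GII": CareProfile(p_inpatient=0.44, inpatient_days=3.6,
                           p_outpatient=0.22, outpatient_visits=1.9,
                           source="Sargeant et al. 2008; Caudle et al. 2009"),
        "AOM": CareProfile(p_care_seeking=0.94, episodes_per_year=2.2,
                           source="Dube et al. 2011"),
        "NEC": CareProfile(p_inpatient=1.0, inpatient_days=32.9,
                           surgical_fraction=0.31,
                           source="all NEC cases treated in NICU; "
                                  "Rees et al. 2010 surgical split; OCCI"),
        "ALL": CareProfile(source="phase uptakes in cost schedule"),
        "obesity": CareProfile(),
        "asthma": CareProfile(),
    }

    costs: dict[str, CostSchedule] = {
        "LRTI": CostSchedule(
            rule="inpatient-outpatient",
            inpatient_unit=usd(911, 222, 8112, "OCCI"),
            outpatient_unit=usd(166, 99, 11_660, "OCCI"),
        ),
        "GII": CostSchedule(
            rule="inpatient-outpatient",
            inpatient_unit=usd(1055, 810, 9088, "OCCI"),
            outpatient_unit=usd(166, 144, 1338, "OCCI"),
        ),
        "AOM": CostSchedule(
            rule="episodes-per-case",
            per_case=usd(97.71, 87, 1919, "OCCI"),
        ),
        "NEC": CostSchedule(
            rule="per-case",
            per_case=usd(60_326, 42_035, 87_658, "OCCI, per NICU-treated case"),
        ),
        "ALL": CostSchedule(
            rule="phase-costs",
            phase_costs={"pre-diagnosis": 3_919.70, "initial": 125_034.0,
                         "continuing": 17_141.6, "terminal": 345_759.1},
            phase_uptake={"pre-diagnosis": 0.92, "initial": 0.92,
                          "continuing": 0.85, "terminal": 0.18},
        ),
        "obesity": CostSchedule(
            rule="annual-excess",
            annual_excess=usd(305.72, 241.39, 374.04, "Ling et al. 2022"),
            years=14,
        ),
        "asthma": CostSchedule(
            rule="annual-excess",
            annual_excess=usd(828.86, 761.67, 1304.75, "Ungar & Coyte 2001"),
            years=14,
            onset_bands=[OnsetBand(weight=0.399, midpoint_age=1.5),
                         OnsetBand(weight=0.429, midpoint_age=5.5),
                         OnsetBand(weight=0.172, midpoint_age=10.0)],
        ),
    }

    return ParameterSet(
        cohort=cohort, rates=rates, diseases=diseases, care=care,
        costs=costs, discount_rate=0.03, currency=CurrencyAdjustment())


def load_parameters(source: str | Path | dict, *,
                    use_defaults: bool = False) -> ParameterSet:
    """Load and validate a parameter set from YAML/JSON or a mapping.

    Parameters
    ----------
    source
        A path to a YAML or JSON document, a YAML/JSON string, or an
        already-parsed mapping with the top-level keys ``cohort``, ``rates``,
        ``diseases``, ``care``, ``costs``, ``discount_rate``, ``currency``.
    use_defaults
        When True, keys absent from the document fall back to the packaged
        Ontario 2019 defaults; when False (default) the document must be
        complete.

    Raises
    ------
    pydantic.ValidationError
        Naming the offending key, for any schema or range violation.
    """
    if isinstance(source, dict):
        doc = source
    else:
        if isinstance(source, Path):
            text = source.read_text()
        elif "\n" not in source and Path(source).exists():
            text = Path(source).read_text()
        else:
            text = source
        doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise TypeError("parameter document must be a mapping")
    if use_defaults:
        base = default_ontario_2019().model_dump(mode="json")
        doc = _deep_merge(base, doc)
    return ParameterSet.model_validate(doc)


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


def dump_parameters(params: ParameterSet, path: str | Path | None = None,
                    fmt: Literal["yaml", "json"] = "yaml") -> str:
    """Serialize a parameter set; round-trips through load_parameters."""
    doc = params.model_dump(mode="json")
    text = (json.dumps(doc, indent=2, sort_keys=True) if fmt == "json"
            else yaml.safe_dump(doc, sort_keys=True))
    if path is not None:
        Path(path).write_text(text)
    return text


def adjust_cost(amount: float, adj: CurrencyAdjustment) -> float:
    """Convert a source-currency amount to target-year USD.

    Pure multiplication: ``amount × inflation_factor × fx_rate``; linear in
    ``amount`` by construction.
    """
    if amount < 0:
        raise ValueError("cost amounts must be non-negative")
    return amount * adj.inflation_factor * adj.fx_rate


def parameter_schema() -> dict:
    """The JSON Schema for the configuration document."""
    return ParameterSet.model_json_schema()


def write_schema_file(path: str | Path) -> None:
    Path(path).write_text(json.dumps(parameter_schema(), indent=2))


def packaged_schema_path() -> Path:
    """Path of the JSON Schema file shipped with the package."""
    return Path(resources.files("bfcost") / "data" / "parameters.schema.json")
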
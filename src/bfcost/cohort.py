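"""Reference populations: the mortality-adjusted birth cohort, the
early-preterm sub-cohort, and feeding-status splits.

Counts are expected values and therefore fractional; rounding to whole
infants happens only when tables are written.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["Cohort", "FeedingSplit", "reference_population",
           "early_preterm_population", "feeding_split"]


@dataclass(frozen=True)
class Cohort:
    """A (possibly fractional) count of infants with a descriptive label."""

    size: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.size < 0:
            raise ValueError("cohort size must be non-negative")


@dataclass(frozen=True)
class FeedingSplit:
    """Breastfed (exposed) and formula-fed (unexposed) sub-counts."""

    bf: float
    ff: float

    @property
    def total(self) -> float:
        return self.bf + self.ff


def reference_population(live_births: float,
                         infant_mortality_per_1000: float,
                         neonatal_mortality_per_1000: float) -> Cohort:
    """Mortality-adjusted birth cohort.

    Infant and neonatal death rates are subtracted additively:
    ``live_births × (1 − (infant + neonatal)/1000)``.
    """
    if min(live_births, infant_mortality_per_1000,
           neonatal_mortality_per_1000) < 0:
        raise ValueError("inputs must be non-negative")
    combined = infant_mortality_per_1000 + neonatal_mortality_per_1000
    if combined >= 1000:
        raise ValueError("combined mortality must be below 1000 per 1000")
    size = live_births * (1.0 - combined / 1000.0)
    return Cohort(size, "live-birth cohort, mortality-adjusted")


def early_preterm_population(live_births: float, preterm_rate: float,
                             early_preterm_fraction: float) -> Cohort:
    """Early-preterm (<32 weeks) sub-cohort: ``births × preterm × early``.

    Deliberately not mortality-adjusted — the NICU sub-cohort chain runs
    from raw live births.
    """
    if live_births < 0:
        raise ValueError("live_births must be non-negative")
    for name, p in (("preterm_rate", preterm_rate),
                    ("early_preterm_fraction", early_preterm_fraction)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0,1], got {p}")
    return Cohort(live_births * preterm_rate * early_preterm_fraction,
                  "early-preterm sub-cohort (<32 weeks)")


def feeding_split(cohort: Cohort, bf_rate: float) -> FeedingSplit:
    """Split a cohort into breastfed and formula-fed groups."""
    if not 0.0 <= bf_rate <= 1.0:
        raise ValueError(f"bf_rate must be in [0,1], got {bf_rate}")
    return FeedingSplit(bf=cohort.size * bf_rate,
                        ff=cohort.size * (1.0 - bf_rate))
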
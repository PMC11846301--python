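"""Care episodes, annual treatment costs, and discounted childhood costs."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from bfcost import (CareProfile, CostSchedule, DiscountSpec, ParameterValue,
                    annual_treatment_cost, annuity_due, care_episodes,
                    childhood_cost, childhood_cost_all,
                    childhood_cost_annual_excess, discount_stream)
from bfcost.params import OnsetBand

LRTI_CARE = CareProfile(p_inpatient=0.06, inpatient_days=3.0,
                        p_outpatient=0.23, outpatient_visits=1.9)
GII_CARE = CareProfile(p_inpatient=0.44, inpatient_days=3.6,
                       p_outpatient=0.22, outpatient_visits=1.9)
AOM_CARE = CareProfile(p_care_seeking=0.94, episodes_per_year=2.2)

GII_COSTS = CostSchedule(
    rule="inpatient-outpatient",
    inpatient_unit=ParameterValue(point=1055, low=810, high=9088),
    outpatient_unit=ParameterValue(point=166, low=144, high=1338))
AOM_COSTS = CostSchedule(rule="episodes-per-case",
                         per_case=ParameterValue(point=97.71))
NEC_COSTS = CostSchedule(rule="per-case",
                         per_case=ParameterValue(point=60_326))
ALL_COSTS = CostSchedule(
    rule="phase-costs",
    phase_costs={"pre-diagnosis": 3_919.70, "initial": 125_034.0,
                 "continuing": 17_141.6, "terminal": 345_759.1},
    phase_uptake={"pre-diagnosis": 0.92, "initial": 0.92,
                  "continuing": 0.85, "terminal": 0.18})


class TestCareEpisodes:
    def test_lrti_hospitalizations(self):
        hosp, _ = care_episodes(32_852.6, LRTI_CARE)
        assert hosp == pytest.approx(1_971.2, abs=0.05)

    def test_gii_pair(self):
        hosp, visits = care_episodes(27_524.5, GII_CARE)
        assert hosp == pytest.approx(12_110.8, abs=0.05)
        assert visits == pytest.approx(11_505.2, abs=0.05)

    def test_aom_uses_care_seeking_episodes(self):
        _, visits = care_episodes(1_000, AOM_CARE)
        assert visits == pytest.approx(1_000 * 0.94 * 2.2)

    def test_zero_cases(self):
        assert care_episodes(0, GII_CARE) == (0, 0)


class TestAnnualTreatmentCost:
    def test_gii_reproduces_published_total(self):
        # costing validated from the published 27,883-case count
        cost = annual_treatment_cost(27_883, GII_CARE, GII_COSTS)
        assert cost == pytest.approx(48_531_464, rel=2e-5)

    def test_aom_reproduces_published_total(self):
        cost = annual_treatment_cost(43_174, AOM_CARE, AOM_COSTS)
        assert cost == pytest.approx(8_723_962, rel=1e-5)

    def test_nec_reproduces_published_total(self):
        cost = annual_treatment_cost(76.4618, CareProfile(p_inpatient=1.0),
                                     NEC_COSTS)
        assert cost == pytest.approx(4_612_636, rel=1e-5)

    def test_per_stay_switch_drops_length_of_stay_factor(self):
        per_day = annual_treatment_cost(1_000, GII_CARE, GII_COSTS)
        per_stay = annual_treatment_cost(
            1_000, GII_CARE, GII_COSTS.model_copy(update={"per_stay": True}))
        # inpatient component shrinks by the 3.6-day stay factor
        inpatient_day = 1_000 * 0.44 * 3.6 * 1055
        outpatient = 1_000 * 0.22 * 1.9 * 166
        assert per_day == pytest.approx(inpatient_day + outpatient)
        assert per_stay == pytest.approx(inpatient_day / 3.6 + outpatient)

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError, match="rule"):
            annual_treatment_cost(10, GII_CARE, GII_COSTS, rule="bogus")

    @given(cases=st.floats(0, 1e6), k=st.floats(0, 100))
    def test_linearity_in_cases(self, cases, k):
        base = annual_treatment_cost(cases, GII_CARE, GII_COSTS)
        assert annual_treatment_cost(k * cases, GII_CARE, GII_COSTS
                                     ) == pytest.approx(k * base, rel=1e-12,
                                                        abs=1e-6)

    def test_low_point_high_schedules_ordered(self):
        def at(bound):
            doc = GII_COSTS.model_dump()
            for field in ("inpatient_unit", "outpatient_unit"):
                doc[field]["point"] = doc[field][bound]
            return annual_treatment_cost(1_000, GII_CARE,
                                         CostSchedule.model_validate(doc))
        low, mid, high = at("low"), annual_treatment_cost(
            1_000, GII_CARE, GII_COSTS), at("high")
        assert low <= mid <= high


class TestDiscounting:
    def test_unit_annuity_due_14_years(self):
        pv = discount_stream([(t, 1.0) for t in range(14)],
                             DiscountSpec(rate=0.03))
        assert pv == pytest.approx(annuity_due(14, 0.03), abs=1e-12)
        assert pv == pytest.approx(11.634955, abs=1e-6)

    def test_zero_rate_recovers_sum(self):
        payments = [(t, 2.5) for t in range(14)]
        assert discount_stream(payments, DiscountSpec(rate=0.0)) == 35.0
        assert annuity_due(14, 0.0) == 14

    def test_single_immediate_payment(self):
        assert discount_stream([(0, 123.0)], DiscountSpec(rate=0.07)) == 123.0

    @given(rate=st.floats(0.001, 0.2), years=st.integers(1, 40))
    def test_discounted_below_undiscounted(self, rate, years):
        payments = [(t, 1.0) for t in range(years)]
        pv = discount_stream(payments, DiscountSpec(rate=rate))
        assert 0 < pv <= years
        assert pv == pytest.approx(annuity_due(years, rate), rel=1e-12)

    def test_negative_payment_rejected(self):
        with pytest.raises(ValueError):
            discount_stream([(0, -1.0)])


class TestChildhoodCosts:
    def test_all_per_case_cost(self):
        assert childhood_cost_all(1.0, ALL_COSTS) == pytest.approx(
            195_444.4, abs=0.1)

    def test_all_zero_cases_and_zero_uptake(self):
        assert childhood_cost_all(0.0, ALL_COSTS) == 0
        zeroed = ALL_COSTS.model_copy(update={
            "phase_uptake": {k: 0.0 for k in ALL_COSTS.phase_uptake}})
        assert childhood_cost_all(1.0, zeroed) == 0

    def test_obesity_annuity_path(self):
        cost = childhood_cost_annual_excess(1.0, 305.72, 14,
                                            DiscountSpec(rate=0.03))
        assert cost == pytest.approx(305.72 * annuity_due(14, 0.03), rel=1e-12)
        undiscounted = childhood_cost_annual_excess(1.0, 305.72, 14,
                                                    DiscountSpec(rate=0.0))
        assert undiscounted == pytest.approx(14 * 305.72)
        assert cost < undiscounted

    def test_asthma_onset_bands_against_direct_sum(self):
        bands = [OnsetBand(weight=0.399, midpoint_age=1.5),
                 OnsetBand(weight=0.429, midpoint_age=5.5),
                 OnsetBand(weight=0.172, midpoint_age=10.0)]
        spec = DiscountSpec(rate=0.03)
        cost = childhood_cost_annual_excess(1.0, 828.86, 14, spec, bands)
        # independent oracle: enumerate each band's payment ages directly
        expected = 0.0
        for weight, onset in ((0.399, 1.5), (0.429, 5.5), (0.172, 10.0)):
            age = onset
            while age <= 18.0:
                expected += weight * 828.86 / 1.03 ** age
                age += 1.0
        assert cost == pytest.approx(expected, rel=1e-12)
        # later onset accrues fewer years: per-case cost below full annuity
        assert cost < 828.86 * annuity_due(18, 0.03)

    def test_dispatch_by_rule(self):
        assert childhood_cost(2.0, ALL_COSTS) == pytest.approx(
            2 * childhood_cost_all(1.0, ALL_COSTS))
        with pytest.raises(ValueError):
            childhood_cost(1.0, NEC_COSTS)
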
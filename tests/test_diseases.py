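"""Attributable-case computation: differential incidence, group-incidence
chains, and scenario differencing."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from bfcost import (CaseCount, Cohort, GroupIncidenceDisease, ModelWarning,
                    OddsRatioDisease, ParameterValue,
                    annual_cases_group_incidence, attributable_cases_or,
                    cases_averted, differential_incidence,
                    nec_attributable_cases)

LRTI = GroupIncidenceDisease(incidence_ff=0.37, incidence_bf=0.25)
GII = GroupIncidenceDisease(incidence_ff=0.31, incidence_bf=0.14)
NEC = GroupIncidenceDisease(incidence_ff=0.07, incidence_bf=0.01)
REF = Cohort(139_388.5638)


def _or_disease(s, r, years=1.0, r_low=None, r_high=None):
    return OddsRatioDisease(
        overall_incidence=s,
        odds_ratio=ParameterValue(point=r, low=r_low, high=r_high,
                                  units="odds-ratio"),
        exposure_years=years)


class TestDifferentialIncidence:
    def test_obesity_partition(self):
        with pytest.warns(ModelWarning):  # s = 0.131 strains the OR≈RR step
            res = differential_incidence(0.131, 0.363, 0.66)
        assert res.x == pytest.approx(0.149444, abs=5e-6)
        assert res.xr == pytest.approx(0.098633, abs=5e-6)

    def test_null_effect_collapses_groups(self):
        res = differential_incidence(0.05, 0.4, 1.0)
        assert res.x == res.xr == pytest.approx(0.05)

    def test_no_exposed_group(self):
        assert differential_incidence(0.05, 0.0, 0.7).x == pytest.approx(0.05)

    @pytest.mark.parametrize("s, b, r", [
        (1.2, 0.5, 0.7), (0.05, 1.5, 0.7), (0.05, 0.5, 0.0),
        (0.05, 0.5, -1.0)])
    def test_invalid_inputs_rejected(self, s, b, r):
        with pytest.raises(ValueError):
            differential_incidence(s, b, r)

    @given(s=st.floats(0, 0.1), b=st.floats(0, 1),
           r=st.floats(0.05, 5))
    def test_recombination_identity(self, s, b, r):
        res = differential_incidence(s, b, r)
        assert b * res.xr + (1 - b) * res.x == pytest.approx(
            s, rel=1e-12, abs=1e-15)


class TestGroupIncidenceCases:
    def test_lrti_formula_fed_cases(self):
        cases = annual_cases_group_incidence(REF, 0.363, LRTI)
        assert cases.cases == pytest.approx(32_852.5, abs=0.2)
        assert cases.convention == "ff-group-cases"

    def test_gii_formula_fed_cases(self):
        cases = annual_cases_group_incidence(REF, 0.363, GII)
        assert cases.cases == pytest.approx(27_525.1, abs=0.2)

    def test_zero_incidence(self):
        zero = GroupIncidenceDisease(incidence_ff=0.0, incidence_bf=0.0)
        assert annual_cases_group_incidence(REF, 0.5, zero).cases == 0

    def test_conventions_are_consistent(self):
        ff = annual_cases_group_incidence(REF, 0.363, LRTI, "ff-group-cases")
        total = annual_cases_group_incidence(REF, 0.363, LRTI, "total-cases")
        excess = annual_cases_group_incidence(REF, 0.363, LRTI, "excess-cases")
        bf_cases = REF.size * 0.363 * LRTI.incidence_bf
        assert total.cases == pytest.approx(ff.cases + bf_cases)
        assert excess.cases == pytest.approx(
            REF.size * (1 - 0.363) * (0.37 - 0.25))

    @given(scale=st.floats(0.01, 100))
    def test_scale_equivariance(self, scale):
        base = annual_cases_group_incidence(REF, 0.363, LRTI).cases
        scaled = annual_cases_group_incidence(
            Cohort(REF.size * scale), 0.363, LRTI).cases
        assert scaled == pytest.approx(scale * base, rel=1e-12)


class TestNecChain:
    def test_current_rate(self):
        cases = nec_attributable_cases(140_541, 0.081, 0.143, 0.329, NEC)
        assert cases.cases == pytest.approx(76.46, abs=0.01)

    def test_counterfactual_rate(self):
        cases = nec_attributable_cases(140_541, 0.081, 0.143, 0.649, NEC)
        assert cases.cases == pytest.approx(40.00, abs=0.01)

    def test_all_human_milk_fed(self):
        assert nec_attributable_cases(140_541, 0.081, 0.143, 1.0, NEC).cases == 0


class TestOddsRatioCases:
    def test_null_odds_ratio(self):
        assert attributable_cases_or(REF, 0.4, _or_disease(0.05, 1.0)).cases == 0

    def test_empty_cohort(self):
        assert attributable_cases_or(Cohort(0), 0.4,
                                     _or_disease(0.05, 0.7)).cases == 0

    def test_obesity_excess_cases(self):
        with pytest.warns(ModelWarning):
            cases = attributable_cases_or(REF, 0.363, _or_disease(0.131, 0.66))
        assert cases.cases == pytest.approx(4_511.5, abs=0.5)
        assert cases.convention == "excess-cases"

    def test_exposure_years_scale_person_year_incidence(self):
        one = attributable_cases_or(REF, 0.646, _or_disease(7e-5, 0.84, 1.0))
        five = attributable_cases_or(REF, 0.646, _or_disease(7e-5, 0.84, 5.0))
        assert five.cases == pytest.approx(5 * one.cases)

    def test_anti_protective_clamped_with_warning(self):
        with pytest.warns(ModelWarning, match="clamped"):
            cases = attributable_cases_or(REF, 0.4, _or_disease(0.05, 1.3))
        assert cases.cases == 0


class TestCasesAverted:
    def test_nec_savings(self):
        current = nec_attributable_cases(140_541, 0.081, 0.143, 0.329, NEC)
        counterfactual = nec_attributable_cases(140_541, 0.081, 0.143, 0.649,
                                                NEC)
        assert cases_averted(current, counterfactual).cases == pytest.approx(
            36.46, abs=0.01)

    def test_identical_scenarios(self):
        c = CaseCount(10.0)
        assert cases_averted(c, c).cases == 0

    def test_convention_mismatch_rejected(self):
        with pytest.raises(ValueError, match="convention"):
            cases_averted(CaseCount(5, "ff-group-cases"),
                          CaseCount(3, "excess-cases"))

    def test_negative_difference_clamped_with_warning(self):
        with pytest.warns(ModelWarning, match="clamped"):
            out = cases_averted(CaseCount(3.0), CaseCount(5.0))
        assert out.cases == 0

    @given(b=st.floats(0.0, 1.0), bump=st.floats(0.0, 1.0))
    def test_averted_monotone_in_counterfactual_rate(self, b, bump):
        """For a protective effect, raising the counterfactual rate never
        reduces cases averted, and equal rates avert nothing."""
        b_cf = min(b + bump, 1.0)
        current = annual_cases_group_incidence(REF, b, LRTI)
        at_cf = annual_cases_group_incidence(REF, b_cf, LRTI)
        averted = cases_averted(current, at_cf).cases
        assert averted >= 0
        if b_cf == b:
            assert averted == 0
        higher = annual_cases_group_incidence(REF, min(b_cf + 0.01, 1.0), LRTI)
        assert cases_averted(current, higher).cases >= averted - 1e-9
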
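"""Covariate model: maturation, Schwartz eGFR, allometry, unit handling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tobrapk.covariate_model import (AgeGroup, CovariateError, PatientCovariates,
                                     UMOL_PER_MGDL, creatinine_mgdl,
                                     egfr_schwartz, maturation, pma_weeks,
                                     typical_cl, typical_v)
from tobrapk.pk_core import PopulationParameters


class TestPmaAndMaturation:
    @pytest.mark.parametrize("age,ga,expected", [
        (0.0, 40.0, 40.0),
        (2.0, 40.0, 144.0),
        (13.3, 40.0, 731.6),
    ])
    def test_pma(self, age, ga, expected):
        assert pma_weeks(age, ga) == pytest.approx(expected)

    def test_negative_age_rejected(self):
        with pytest.raises(CovariateError):
            pma_weeks(-0.1)

    def test_half_maximal_at_tm50(self):
        assert maturation(47.7) == pytest.approx(0.5)

    def test_two_year_old_nearly_mature(self):
        assert maturation(144.0) == pytest.approx(0.977, abs=5e-4)

    def test_asymptote_below_one(self):
        m = maturation(1e4)
        assert 0.999 < m < 1.0

    @given(st.floats(min_value=1.0, max_value=5000.0),
           st.floats(min_value=1.001, max_value=2.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_strictly_increasing_and_bounded(self, pma, factor):
        lo, hi = maturation(pma), maturation(pma * factor)
        assert 0.0 < lo < hi < 1.0

    def test_nonpositive_pma_rejected(self):
        with pytest.raises(CovariateError):
            maturation(0.0)


class TestEgfr:
    def test_formula_constant(self):
        assert egfr_schwartz(1.0, 1.0, "mg/dL") == pytest.approx(41.3)

    def test_study_median_patient(self):
        # median height/creatinine reproduce the cohort's median eGFR ~127
        assert egfr_schwartz(1.53, 43.0, "umol/L") == pytest.approx(129.9, abs=0.05)

    def test_missing_unit_rejected(self):
        with pytest.raises(CovariateError):
            egfr_schwartz(1.5, 50.0, None)
        with pytest.raises(CovariateError):
            creatinine_mgdl(50.0, "mol")

    def test_unit_round_trip_is_identity(self):
        value = 43.0
        mgdl = creatinine_mgdl(value, "umol/L")
        assert float(mgdl) * UMOL_PER_MGDL == pytest.approx(value, rel=1e-12)


class TestTypicalClearance:
    def test_reference_patient_reproduces_theta(self, reference_covariates, pop):
        assert typical_cl(reference_covariates, pop) == pytest.approx(6.17, abs=0.005)

    def test_one_year_old_worked_example(self, pop):
        cov = PatientCovariates(age=1.0, weight=10.0, height=0.75,
                                serum_creatinine=20.0, creatinine_unit="umol/L")
        assert typical_cl(cov, pop) == pytest.approx(1.579, abs=5e-4)

    def test_weight_power_law(self, pop):
        base = PatientCovariates(age=18.0, weight=35.0, height=1.6,
                                 serum_creatinine=50.0, creatinine_unit="umol/L")
        double = PatientCovariates(age=18.0, weight=70.0, height=1.6,
                                   serum_creatinine=50.0, creatinine_unit="umol/L")
        ratio = typical_cl(double, pop) / typical_cl(base, pop)
        assert ratio == pytest.approx(2 ** 0.663, rel=1e-9)

    @pytest.mark.parametrize("field,lo,hi", [
        ("weight", 10.0, 11.0),
        ("age", 1.0, 1.5),
    ])
    def test_monotone_in_weight_and_age(self, field, lo, hi, pop):
        def make(**kw):
            base = dict(age=1.0, weight=10.0, height=0.75,
                        serum_creatinine=20.0, creatinine_unit="umol/L")
            base.update(kw)
            return PatientCovariates(**base)
        assert typical_cl(make(**{field: hi}), pop) > typical_cl(make(**{field: lo}), pop)

    def test_monotone_in_egfr(self, pop):
        # lower creatinine -> higher eGFR -> higher clearance
        hi = PatientCovariates(age=8.0, weight=25.0, height=1.3,
                               serum_creatinine=30.0, creatinine_unit="umol/L")
        lo = PatientCovariates(age=8.0, weight=25.0, height=1.3,
                               serum_creatinine=60.0, creatinine_unit="umol/L")
        assert typical_cl(hi, pop) > typical_cl(lo, pop)


class TestTypicalVolume:
    @pytest.mark.parametrize("weight,expected,tol", [
        (70.0, 15.5, 1e-9),
        (43.8, 10.935, 5e-3),
    ])
    def test_values(self, weight, expected, tol, pop):
        assert typical_v(weight, pop) == pytest.approx(expected, abs=tol)

    def test_power_law_doubling(self, pop):
        w = 70.0 * 2 ** (1 / 0.744)
        assert typical_v(w, pop) == pytest.approx(31.0, abs=5e-3)

    def test_nonpositive_weight_rejected(self, pop):
        with pytest.raises(CovariateError):
            typical_v(0.0, pop)


class TestAgeGroups:
    @pytest.mark.parametrize("age,label", [
        (0.0, "<2"), (1.999, "<2"),
        (2.0, "2-12"), (7.0, "2-12"), (12.0, "2-12"),
        (12.001, ">12"), (19.3, ">12"),
    ])
    def test_partition(self, age, label):
        assert AgeGroup.of(age).value == label

    def test_negative_age_rejected(self):
        with pytest.raises(CovariateError):
            AgeGroup.of(-1.0)


class TestPatientCovariates:
    def test_out_of_range_age_rejected(self):
        with pytest.raises(CovariateError):
            PatientCovariates(age=25.0, weight=70.0, height=1.7,
                              serum_creatinine=60.0, creatinine_unit="umol/L")

    def test_gestational_age_bounds(self):
        with pytest.raises(CovariateError):
            PatientCovariates(age=1.0, weight=10.0, height=0.75,
                              serum_creatinine=20.0, creatinine_unit="umol/L",
                              gestational_age=20.0)

    def test_unit_tag_required(self):
        with pytest.raises(CovariateError):
            PatientCovariates(age=1.0, weight=10.0, height=0.75,
                              serum_creatinine=20.0, creatinine_unit="grams")
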
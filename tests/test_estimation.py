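"""Mixed-effects estimation: M6 rule, objective function, LRT, small recovery."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from tobrapk.covariate_model import typical_cl_arrays, typical_v
from tobrapk.estimation import (EstimationError, EstimationSettings,
                                assign_intervals, fit, lrt_covariate_step,
                                objective_function, preprocess_m6)
from tobrapk.pk_core import (ConcentrationRecord, DoseRegimen,
                             IndividualParameters, PopulationParameters,
                             concentration)
from tobrapk.synthetic_data import CohortSpec, TDMDesign, generate_cohort, simulate_tdm


def m6_oracle(pattern):
    """Hand enumeration of the M6 rule for a BLQ flag pattern.

    Walk the records of one dose interval in time order keeping a 'in BLQ
    run' switch: the first BLQ of a run is imputed at 0.3, later ones in the
    run are dropped, and any quantifiable value resets the switch.
    """
    kept, in_run = [], False
    for i, is_blq in enumerate(pattern):
        if not is_blq:
            kept.append(("obs", i))
            in_run = False
        elif not in_run:
            kept.append(("imputed", i))
            in_run = True
    return kept


class TestM6:
    @pytest.mark.parametrize("pattern", list(itertools.product([False, True],
                                                               repeat=3)))
    def test_all_length3_patterns_match_hand_enumeration(self, pattern):
        values = [2.1, 1.5, 0.9]
        records = [ConcentrationRecord(time=float(i),
                                       concentration=None if b else values[i],
                                       blq=b, interval_index=0)
                   for i, b in enumerate(pattern)]
        out = preprocess_m6(records, lloq=0.6)
        expected = m6_oracle(pattern)
        assert len(out) == len(expected)
        for rec, (kind, i) in zip(out, expected):
            assert rec.time == float(i)
            if kind == "imputed":
                assert rec.concentration == pytest.approx(0.3)
                assert rec.blq
            else:
                assert rec.concentration == values[i]
                assert not rec.blq

    def test_never_modifies_quantifiable_and_never_grows(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = rng.integers(1, 8)
            pattern = rng.random(n) < 0.4
            records = [ConcentrationRecord(time=float(i),
                                           concentration=None if b else 5.0 + i,
                                           blq=bool(b), interval_index=int(i // 3))
                       for i, b in enumerate(pattern)]
            out = preprocess_m6(records)
            assert len(out) <= len(records)
            originals = {r.time: r for r in records}
            for rec in out:
                if not rec.blq:
                    assert rec == originals[rec.time]

    def test_dataframe_variant_sequences_per_interval(self):
        df = pd.DataFrame({
            "ID": [1] * 6,
            "TIME": [0.0, 1.0, 2.0, 24.0, 25.0, 26.0],
            "EVID": [1, 0, 0, 1, 0, 0],
            "AMT": [100, np.nan, np.nan, 100, np.nan, np.nan],
            "DUR": [0.5] * 6,
            "DV": [np.nan, np.nan, np.nan, np.nan, 1.5, np.nan],
            "MDV": [1, 1, 1, 1, 0, 1],
            "BLQ": [0, 1, 1, 0, 0, 1],
        })
        out = preprocess_m6(df)
        obs = out[out["EVID"] == 0]
        # first interval: BLQ run collapses to one imputed 0.3
        # second interval: quantifiable 1.5 then a fresh BLQ run -> imputed
        assert obs["DV"].tolist() == pytest.approx([0.3, 1.5, 0.3])
        assert obs["MDV"].tolist() == [0, 0, 0]

    def test_observation_before_any_dose_rejected(self):
        df = pd.DataFrame({
            "ID": [1, 1], "TIME": [0.5, 1.0], "EVID": [0, 1],
            "AMT": [np.nan, 100.0], "DUR": [np.nan, 0.5],
            "DV": [1.0, np.nan], "MDV": [0, 1], "BLQ": [0, 0],
        })
        with pytest.raises(EstimationError):
            assign_intervals(df)


def _reference_dataset(times, y, n_copies=1):
    """Dataset at the reference covariates so typical CL/V equal the thetas."""
    rows = []
    scr = 41.3 * 1.70 / 127.3 * 88.4  # umol/L giving eGFR exactly 127.3
    for sid in range(1, n_copies + 1):
        rows.append((sid, 0.0, 1, 586.15, 0.5, np.nan, 1, 0, 18.0, 70.0, 1.70, scr, 40.0))
        for t, dv in zip(times, y):
            rows.append((sid, t, 0, np.nan, np.nan, dv, 0, 0,
                         18.0, 70.0, 1.70, scr, 40.0))
    return pd.DataFrame(rows, columns=["ID", "TIME", "EVID", "AMT", "DUR", "DV",
                                       "MDV", "BLQ", "AGE_YR", "WT_KG", "HT_M",
                                       "SCR_UMOLL", "GA_WK"])


class TestObjectiveFunction:
    def test_omega_zero_equals_weighted_least_squares_deviance(self, pop):
        # with etas pinned the OFV has the closed form
        # sum[(y-f)^2/g + ln g] + n*ln(2*pi), hand-computable from the
        # structural model prediction
        frozen = pop.with_(omega_CL=0.0, omega_V=0.0, omega_D1=0.0)
        times = [1.5, 6.0]
        tvcl = float(typical_cl_arrays(18.0, 70.0, 127.3, frozen))
        ind = IndividualParameters(CL=tvcl, V=15.5, D1=frozen.theta_D1)
        regimen = DoseRegimen(dose=586.15, infusion_duration=frozen.theta_D1,
                              n_doses=1)
        f = np.array([concentration(ind, regimen, t) for t in times])
        y = f * 1.1
        df = _reference_dataset(times, y)
        g = frozen.sigma_add ** 2 + frozen.sigma_prop ** 2 * f ** 2
        expected = float(np.sum((y - f) ** 2 / g + np.log(g)) + 2 * math.log(2 * math.pi))
        got = objective_function(df, frozen)
        assert got == pytest.approx(expected, rel=1e-6)

    def test_duplicating_subjects_doubles_ofv(self, pop):
        times = [1.5, 6.0]
        y = [20.0, 4.0]
        one = objective_function(_reference_dataset(times, y, n_copies=1), pop)
        two = objective_function(_reference_dataset(times, y, n_copies=2), pop)
        assert two == pytest.approx(2 * one, rel=1e-8)


class TestLrt:
    def test_drop_four_is_significant(self):
        dec = lrt_covariate_step(100.0, 96.0)
        assert dec.significant
        assert dec.p_value == pytest.approx(0.0455, abs=5e-4)

    def test_drop_at_threshold_is_not_significant(self):
        dec = lrt_covariate_step(100.0, 96.16)
        assert not dec.significant
        assert dec.p_value == pytest.approx(0.0500, abs=6e-4)

    def test_zero_drop(self):
        dec = lrt_covariate_step(100.0, 100.0)
        assert not dec.significant and dec.p_value == 1.0

    def test_invariant_to_ofv_offset(self):
        a = lrt_covariate_step(100.0, 95.0)
        b = lrt_covariate_step(1100.0, 1095.0)
        assert (a.significant, a.p_value) == (b.significant, b.p_value)

    def test_negative_improvement_warns(self):
        dec = lrt_covariate_step(100.0, 103.0)
        assert dec.warning is not None and not dec.significant


class TestFit:
    def test_requires_two_subjects(self, pop):
        df = _reference_dataset([1.5, 6.0], [20.0, 4.0], n_copies=1)
        with pytest.raises(EstimationError):
            fit(df)

    def test_near_deterministic_recovery(self):
        # no between-subject variability, tiny additive noise: the fixed
        # effects must come back almost exactly
        truth = PopulationParameters(omega_CL=0.0, omega_V=0.0, omega_D1=0.0,
                                     sigma_add=0.01, sigma_prop=0.0)
        cohort = generate_cohort(CohortSpec(
            n_per_group={"<2": 7, "2-12": 7, ">12": 6}, seed=77))
        df = simulate_tdm(cohort, truth, TDMDesign(), seed=77)
        settings = EstimationSettings(
            free=("theta_cl", "theta_v", "theta_d1", "sigma_add"),
            init={"omega_cl": 0.0, "omega_v": 0.0, "omega_d1": 0.0,
                  "sigma_prop": 0.0, "sigma_add": 0.05},
        )
        result = fit(df, settings)
        assert result.estimates["theta_cl"] == pytest.approx(6.17, rel=0.02)
        assert result.estimates["theta_v"] == pytest.approx(15.5, rel=0.02)

    def test_truth_start_not_worse_than_default_start(self):
        truth = PopulationParameters(omega_CL=0.0, omega_V=0.0, omega_D1=0.0,
                                     sigma_add=0.01, sigma_prop=0.0)
        cohort = generate_cohort(CohortSpec(
            n_per_group={"<2": 4, "2-12": 3, ">12": 3}, seed=13))
        df = simulate_tdm(cohort, truth, TDMDesign(), seed=13)
        shared = {"omega_cl": 0.0, "omega_v": 0.0, "omega_d1": 0.0,
                  "sigma_prop": 0.0}
        free = ("theta_cl", "theta_v", "theta_d1", "sigma_add")
        from_default = fit(df, EstimationSettings(
            free=free, init={**shared, "sigma_add": 0.05}))
        from_truth = fit(df, EstimationSettings(
            free=free, init={**shared, "theta_cl": 6.17, "theta_v": 15.5,
                             "theta_d1": 0.801, "sigma_add": 0.01}))
        assert from_truth.ofv <= from_default.ofv + 0.5
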
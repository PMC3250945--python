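"""Survival machinery: KM, annual probabilities, RR algebra, extrapolation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from cathcea import registry_synth as rs
from cathcea.config import default_config
from cathcea.survival_model import (AnnualMortality, LifeTable, RRWindow,
                                    RelativeRiskSchedule, annual_probs,
                                    extrapolate, impute_window_rr,
                                    km_estimate,
                                    medical_management_mortality, or_to_rr,
                                    population_mortality,
                                    schedule_from_table3)


def _patients(durations, events):
    n = len(durations)
    return pd.DataFrame({
        "id": range(n), "acs": False, "sex": "male", "age_band": "lt65",
        "anatomy": "left_main", "treatment": "cabg",
        "event_time": durations, "event": events,
        "censor_time": durations})


class TestKaplanMeier:
    def test_hand_product_limit(self):
        # deaths at 1, 2; censorings at 3, 4
        df = _patients([1, 2, 3, 4], [True, True, False, False])
        c = km_estimate(df, {}, years=4)
        assert c.survival[1] == pytest.approx(0.75)
        assert c.survival[2] == pytest.approx(0.50)
        # Greenwood: Var(S(2)) = S^2 (1/(4*3) + 1/(3*2))
        assert c.greenwood_se[2] == pytest.approx(
            0.5 * np.sqrt(1 / 12 + 1 / 6))

    def test_no_deaths_flat(self):
        df = _patients([5, 5, 5], [False] * 3)
        c = km_estimate(df, {}, years=5)
        assert (c.survival == 1.0).all()
        assert (c.greenwood_se == 0.0).all()

    def test_no_censoring_equals_empirical_fraction(self, rng):
        t = rng.exponential(4.0, size=400)
        df = _patients(t, [True] * 400)
        c = km_estimate(df, {}, years=8)
        for year in range(1, 9):
            brute = (t > year).mean()  # surviving fraction, counted directly
            assert c.survival[year] == pytest.approx(brute, abs=1e-12)

    def test_empty_subgroup_names_cell(self):
        df = _patients([1.0], [True])
        with pytest.raises(ValueError, match="sex.*female"):
            km_estimate(df, {"sex": "female"})

    def test_management_filter(self, patients):
        cell = {"acs": True, "sex": "male", "age_band": "lt65",
                "anatomy": "left_main", "management": "revascularized"}
        c = km_estimate(patients, cell, years=10)
        assert c.n > 0
        assert c.survival[0] == 1.0
        assert (np.diff(c.survival) <= 1e-12).all()


class TestAnnualProbs:
    def test_constant_hazard(self):
        curve = km_estimate(_patients([10], [False]), {}, years=2)
        curve = type(curve)(curve.subgroup, np.array([0., 1., 2.]),
                            np.array([1.0, 0.9, 0.81]),
                            np.zeros(3), np.zeros(3), 1)
        m = annual_probs(curve)
        np.testing.assert_allclose(m.q, [0.1, 0.1])
        assert m.source == ("observed", "observed")

    def test_flat_survival_zero_q(self):
        c = km_estimate(_patients([10, 10], [False, False]), {}, years=3)
        m = annual_probs(c)
        assert (m.q == 0.0).all()

    def test_absorbing_after_extinction(self):
        curve = km_estimate(_patients([10], [False]), {}, years=3)
        curve = type(curve)(curve.subgroup, np.arange(4.0),
                            np.array([1.0, 0.5, 0.0, 0.0]),
                            np.zeros(4), np.zeros(4), 1)
        m = annual_probs(curve)
        np.testing.assert_allclose(m.q, [0.5, 1.0, 1.0])

    def test_piecewise_exponential_closed_form(self):
        h = 0.12
        cfg = default_config(seed=17, n_patients=40_000)
        cfg.subgroup_weights = {("male", "lt65"): 1.0}
        cfg.anatomy_prevalence = {("male", "lt65"): {
            "left_main": 1.0, "three_vessel": 0.0, "one_two_vessel": 0.0,
            "normal": 0.0}}
        cfg.treatment_probs = {("male", "lt65", a): (1.0, 1.0) for a in
                               ("left_main", "three_vessel",
                                "one_two_vessel")}
        cfg.treatment_probs[("male", "lt65", "normal")] = (0.0, 0.0)
        cfg.acs_fraction = 0.0
        for key in cfg.hazard_params:
            cfg.hazard_params[key] = ((0.0,), (h,))
        pats = rs.generate_patients(cfg)
        m = annual_probs(km_estimate(pats, {}, years=10))
        q_true = 1 - np.exp(-h)
        for t in range(10):
            n_at = (pats["event_time"] >= t).sum()
            se = np.sqrt(q_true * (1 - q_true) / n_at)
            assert abs(m.q[t] - q_true) < 3 * se


class TestOrToRr:
    def test_null_and_rare_disease_limits(self):
        assert or_to_rr(1.0, 0.3) == 1.0
        assert or_to_rr(2.0, 1e-9) == pytest.approx(2.0, rel=1e-6)

    def test_worked_example_vs_two_by_two(self):
        # OR=2, p0=0.5: implied exposed risk p1 solves odds1 = 2 * odds0
        assert or_to_rr(2.0, 0.5) == pytest.approx(4.0 / 3.0)

    @given(orr=st.floats(0.1, 10), p0=st.floats(0.01, 0.99))
    def test_matches_brute_force_table(self, orr, p0):
        # construct the implied 2x2: odds1 = OR * p0/(1-p0), p1 = odds1/(1+odds1)
        odds1 = orr * p0 / (1 - p0)
        p1 = odds1 / (1 + odds1)
        assert or_to_rr(orr, p0) == pytest.approx(p1 / p0, rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            or_to_rr(0.0, 0.5)
        with pytest.raises(ValueError):
            or_to_rr(2.0, 1.0)


def _const_mortality(q, n=10, tag="observed"):
    return AnnualMortality(np.full(n, q), tuple([tag] * n))


class TestImputeWindowRR:
    def test_identity_when_cumulative_rrs_one(self):
        m = _const_mortality(0.1)
        assert impute_window_rr(1.0, 1.0, m, 5, 10) == pytest.approx(1.0)

    def test_constant_hazard_plugin(self):
        # RR_05=2.33, RR_0,10=1.5 with flat hazard: (15 - 11.65)/5 = 0.67
        m = _const_mortality(1 - np.exp(-0.05))
        rr = impute_window_rr(2.33, 1.5, m, 5, 10)
        assert rr == pytest.approx(0.67, abs=1e-12)

    def test_round_trip_reconstruction(self):
        rng = np.random.default_rng(4)
        m = AnnualMortality(rng.uniform(0.02, 0.2, 10), ("observed",) * 10)
        rr05, rr010 = 1.8, 1.3
        w = impute_window_rr(rr05, rr010, m, 5, 10)
        H5, H10 = m.cumulative_hazard(5), m.cumulative_hazard(10)
        assert rr05 * H5 + w * (H10 - H5) == pytest.approx(rr010 * H10,
                                                           rel=1e-12)

    def test_flat_window_error(self):
        m = AnnualMortality(np.array([0.1] * 5 + [0.0] * 5),
                            ("observed",) * 10)
        with pytest.raises(ValueError, match="no events"):
            impute_window_rr(2.0, 1.5, m, 5, 10)


class TestRelativeRiskSchedule:
    def test_parse_yusuf_left_main(self, tbls):
        s = schedule_from_table3(tbls.table3, "yusuf", "left_main")
        assert [(w.start, w.end, w.rr) for w in s.windows] == [
            (0.0, 5.0, 2.33), (5.0, 10.0, 0.74), (10.0, np.inf, 1.00)]
        assert s.windows[2].source == "assumed"
        assert s.rr_at(3) == 2.33 and s.rr_at(8) == 0.74
        assert s.rr_at(25) == 1.0

    def test_frisc_pooled_across_anatomies(self, tbls):
        for anatomy in ("left_main", "three_vessel", "one_two_vessel"):
            s = schedule_from_table3(tbls.table3, "frisc2", anatomy)
            assert [(w.start, w.end, w.rr) for w in s.windows] == [
                (0.0, 2.0, 1.47), (2.0, 5.0, 0.88), (5.0, np.inf, 1.00)]

    def test_multiplier_spares_assumed_windows(self, tbls):
        s = schedule_from_table3(tbls.table3, "yusuf", "left_main")
        s2 = s.multiplied(0.75)
        assert s2.windows[0].rr == pytest.approx(2.33 * 0.75)
        assert s2.windows[2].rr == 1.00  # assumed terminal window untouched

    def test_extend_first_window(self, tbls):
        s = schedule_from_table3(tbls.table3, "yusuf", "left_main")
        s10 = s.extended_first_window(10.0)
        assert s10.rr_at(8) == 2.33
        assert s10.rr_at(11) == 1.0

    def test_invalid_windows_rejected(self):
        with pytest.raises(ValueError, match="start at 0"):
            RelativeRiskSchedule((RRWindow(1, 5, 1.2),))
        with pytest.raises(ValueError, match="contiguous"):
            RelativeRiskSchedule((RRWindow(0, 5, 1.2), RRWindow(6, 10, 1.0)))
        with pytest.raises(ValueError, match="positive"):
            RelativeRiskSchedule((RRWindow(0, 5, -1.0),))


class TestMedicalManagementMortality:
    def test_rr_one_identity(self):
        m = _const_mortality(0.07)
        s = RelativeRiskSchedule((RRWindow(0, np.inf, 1.0),))
        np.testing.assert_allclose(medical_management_mortality(m, s).q, m.q)

    def test_hazard_scale_doubling(self):
        m = _const_mortality(0.1, n=3)
        s = RelativeRiskSchedule((RRWindow(0, np.inf, 2.0),))
        out = medical_management_mortality(m, s)
        assert out.q[0] == pytest.approx(1 - 0.9 ** 2)
        assert out.source == ("rr-adjusted",) * 3

    def test_inverse_schedule_round_trip(self):
        rng = np.random.default_rng(8)
        m = AnnualMortality(rng.uniform(0.01, 0.3, 12), ("observed",) * 12)
        s = RelativeRiskSchedule((RRWindow(0, 5, 2.33), RRWindow(5, 10, 0.74),
                                  RRWindow(10, np.inf, 1.0)))
        there = medical_management_mortality(m, s)
        back = medical_management_mortality(
            AnnualMortality(there.q, ("observed",) * 12), s.inverted())
        np.testing.assert_allclose(back.q, m.q, atol=1e-12)

    def test_five_year_cumulative_hazard_ratio_exact(self):
        # applying the left-main schedule multiplies the 5-year cumulative
        # hazard by exactly its first-window RR
        rng = np.random.default_rng(9)
        m = AnnualMortality(rng.uniform(0.01, 0.2, 10), ("observed",) * 10)
        s = RelativeRiskSchedule((RRWindow(0, 5, 2.33), RRWindow(5, 10, 0.74),
                                  RRWindow(10, np.inf, 1.0)))
        med = medical_management_mortality(m, s)
        ratio = med.cumulative_hazard(5) / m.cumulative_hazard(5)
        assert ratio == pytest.approx(2.33, rel=1e-12)

    def test_harmful_rr_orders_survival(self):
        m = _const_mortality(0.05)
        s = RelativeRiskSchedule((RRWindow(0, np.inf, 1.6),))
        med = medical_management_mortality(m, s)
        assert (med.survival() <= m.survival() + 1e-15).all()

    def test_absorbing_state_with_protective_rr_warns(self):
        m = AnnualMortality(np.array([0.5, 1.0, 1.0]), ("observed",) * 3)
        s = RelativeRiskSchedule((RRWindow(0, np.inf, 0.5),))
        with pytest.warns(UserWarning, match="absorbing"):
            out = medical_management_mortality(m, s)
        assert out.q[1] == 1.0


class TestExtrapolation:
    def _lifetable(self, a, b):
        ages = np.arange(20, 106)
        rows = []
        for sex in ("male", "female"):
            rows.append(pd.DataFrame({
                "age": ages, "sex": sex,
                "m": np.minimum(0.999, a * np.exp(b * ages))}))
        return LifeTable(pd.concat(rows, ignore_index=True))

    def test_flat_life_table_constant_q(self):
        lt = self._lifetable(1e-3, 0.0)
        m = _const_mortality(0.08)
        out = extrapolate(m, lt, 57, "male", 20)
        np.testing.assert_allclose(out.q[10:], 0.08, rtol=1e-12)
        assert set(out.source[10:]) == {"extrapolated"}

    def test_gompertz_hazard_ratio(self):
        lt = self._lifetable(1e-5, 0.1)
        m = _const_mortality(0.05)
        out = extrapolate(m, lt, 57, "male", 20)
        h = out.hazard()
        assert h[11] / h[10] == pytest.approx(np.exp(0.1), rel=1e-9)

    def test_monotone_transfer(self):
        lt = self._lifetable(2e-5, 0.1)
        m = _const_mortality(0.05)
        out = extrapolate(m, lt, 57, "male", 40)
        assert (np.diff(out.q[10:]) >= -1e-15).all()

    def test_age_range_error(self):
        lt = self._lifetable(1e-5, 0.1)
        with pytest.raises(ValueError, match="life-table range"):
            extrapolate(_const_mortality(0.05), lt, 80, "male", 40)


class TestPopulationMortality:
    def test_identity_vs_life_table(self):
        lt = TestExtrapolation()._lifetable(2e-5, 0.1)
        m = population_mortality(lt, 57, "female", 30)
        for t in (1, 15, 30):
            assert m.q[t - 1] == lt.m(57 + t, "female")
        assert set(m.source) == {"population"}

    def test_life_expectancy_matches_microsimulation(self, rng):
        lt = TestExtrapolation()._lifetable(2e-5, 0.1)
        m = population_mortality(lt, 57, "male", 43)
        le_model = m.survival()[:-1].sum()  # expected whole years lived
        # brute-force cohort: sequential annual Bernoulli survival draws
        n = 200_000
        alive = np.ones(n, bool)
        years = np.zeros(n)
        for q in m.q:
            years += alive
            alive &= rng.random(n) >= q
        assert le_model == pytest.approx(years.mean(), abs=0.1)
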
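"""Bolus calculator, sigmoid refinement, gating logic and closed loop."""

import numpy as np
import pandas as pd
import pytest

from glycloop.bolus import (
    BolusConfig, Branch, adjustment_factor, cgm_trend, final_bolus,
    insulin_on_board, make_adjusted_policy, modified_bolus, sigmoid,
    standard_bolus,
)
from glycloop.cohort import (
    SimScenario, draw_patient, realize_scenario, simulate_patient,
    standard_policy,
)
from glycloop.core_io import BolusEvent, TherapyParams
from glycloop.errors import TrendError

from conftest import T0, constant_trace, make_trace


class TestStandardBolus:
    def test_worked_example(self):
        th = TherapyParams(cr=10.0, cf=30.0, cgm_target=150.0)
        assert standard_bolus(60.0, th, 180.0) == pytest.approx(7.0)

    def test_zero_case(self):
        th = TherapyParams(cr=10.0, cf=30.0, cgm_target=150.0)
        assert standard_bolus(0.0, th, 150.0) == 0.0

    def test_negative_correction_term(self):
        th = TherapyParams(cr=10.0, cf=25.0, cgm_target=150.0)
        assert standard_bolus(50.0, th, 100.0) == pytest.approx(3.0)


class TestSigmoid:
    def test_midpoint(self):
        assert sigmoid(0.0) == 0.5

    def test_symmetry(self):
        for x in (-7.3, -1.0, 0.2, 4.5):
            assert sigmoid(x) + sigmoid(-x) == pytest.approx(1.0, abs=1e-12)

    def test_saturation_overflow_safe(self):
        assert sigmoid(40.0) == pytest.approx(1.0, abs=1e-12)
        assert sigmoid(-750.0) == pytest.approx(0.0, abs=1e-12)


class TestAdjustmentFactor:
    def test_zero_at_reference_in_normalized_mode(self):
        cfg = BolusConfig()
        th = TherapyParams(cr=10.0, cf=cfg.cf_ref, cgm_target=150.0)
        assert adjustment_factor(150.0, th, cfg) == pytest.approx(0.0, abs=1e-12)

    def test_literal_mode_saturates_near_one(self):
        cfg = BolusConfig(sigmoid_mode="literal")
        th = TherapyParams(cr=10.0, cf=40.0, cgm_target=150.0)
        assert adjustment_factor(150.0, th, cfg) == pytest.approx(1.0, abs=1e-12)

    def test_strictly_increasing_in_glucose(self):
        cfg = BolusConfig()
        th = TherapyParams(cr=10.0, cf=50.0)
        values = [adjustment_factor(g, th, cfg) for g in range(60, 300, 20)]
        assert all(a < b for a, b in zip(values, values[1:]))

    def test_bounded_in_open_unit_interval(self):
        cfg = BolusConfig()
        for g in (40, 100, 150, 250, 500):
            for cf in (20, 60, 105, 200):
                th = TherapyParams(cr=8.0, cf=float(cf))
                af = adjustment_factor(float(g), th, cfg)
                assert -1.0 < af < 1.0


class TestModifiedBolus:
    def test_identity_at_zero(self):
        assert modified_bolus(6.0, 0.0) == 6.0

    def test_half_reduction(self):
        assert modified_bolus(6.0, -0.5) == pytest.approx(3.0)

    def test_bounded_for_af_in_unit_interval(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            mib = rng.uniform(0.1, 15)
            af = rng.uniform(-0.999, 0.999)
            assert 0.0 < modified_bolus(mib, af) < 2.0 * mib


class TestTrend:
    def test_linear_decline(self):
        vals = 200.0 - np.arange(72) * 5.0  # -1 mg/dL per minute
        assert cgm_trend(make_trace(vals)) == pytest.approx(-1.0)

    def test_constant_trace(self):
        assert cgm_trend(constant_trace(120.0, 72)) == pytest.approx(0.0)

    def test_noisy_line_recovered(self):
        rng = np.random.default_rng(2)
        slope = 0.8
        t = np.arange(12) * 5.0
        est = []
        for _ in range(40):
            vals = np.concatenate([np.full(60, 100.0),
                                   100.0 + slope * t + rng.normal(0, 2, 12)])
            est.append(cgm_trend(make_trace(vals)))
        # mean estimate within its own standard error of the true slope
        assert np.mean(est) == pytest.approx(slope, abs=3 * np.std(est) / 6)

    def test_too_few_samples(self):
        miss = np.ones(72, bool)
        miss[-1] = False
        tr = make_trace(np.full(72, 100.0), missing=miss)
        with pytest.raises(TrendError):
            cgm_trend(tr)


class TestIob:
    def test_bolus_now_fully_on_board(self):
        assert insulin_on_board([BolusEvent(time=T0, units=5.0)], T0) == 5.0

    def test_linear_decay_halfway(self):
        boluses = [BolusEvent(time=T0, units=5.0)]
        t = T0 + pd.Timedelta(hours=2)
        assert insulin_on_board(boluses, t, dia_hours=4.0) == pytest.approx(2.5)

    def test_expired_after_dia(self):
        boluses = [BolusEvent(time=T0, units=5.0)]
        t = T0 + pd.Timedelta(hours=4, minutes=1)
        assert insulin_on_board(boluses, t, dia_hours=4.0) == 0.0

    def test_future_boluses_ignored(self):
        boluses = [BolusEvent(time=T0 + pd.Timedelta(hours=1), units=5.0)]
        assert insulin_on_board(boluses, T0, dia_hours=4.0) == 0.0


class TestFinalBolus:
    def test_no_event_delivers_mib_unchanged(self):
        rec = final_bolus(b_mod=5.5, mib=6.0, s1_vote=0, s2_vote=0,
                          slope=-1.0, iob=2.0)
        assert rec.b_final == 6.0
        assert rec.branch == Branch.NO_EVENT

    def test_hypo_downward_branch_arithmetic(self):
        cfg = BolusConfig(alpha=1.02)
        rec = final_bolus(b_mod=4.0, mib=5.0, s1_vote=1, s2_vote=0,
                          slope=-0.5, iob=1.0, config=cfg)
        assert rec.b_final == pytest.approx(4.0 * 1.02 - 1.0)
        assert rec.branch == Branch.HYPO_DOWN

    def test_clamped_at_zero(self):
        rec = final_bolus(b_mod=0.5, mib=1.0, s1_vote=1, s2_vote=0,
                          slope=-0.5, iob=2.0)
        assert rec.b_final == 0.0

    def test_hyper_downward_uses_gamma(self):
        cfg = BolusConfig(gamma=1.01)
        rec = final_bolus(b_mod=6.0, mib=6.0, s1_vote=0, s2_vote=1,
                          slope=-0.2, iob=0.5, config=cfg)
        assert rec.b_final == pytest.approx(6.0 * 1.01 - 0.5)
        assert rec.branch == Branch.HYPER_DOWN

    def test_hypo_takes_precedence_over_hyper(self):
        rec = final_bolus(b_mod=6.0, mib=6.0, s1_vote=1, s2_vote=1,
                          slope=-0.2, iob=0.0)
        assert rec.branch == Branch.HYPO_DOWN

    def test_zero_slope_follows_upward_branch(self):
        rec = final_bolus(b_mod=4.5, mib=6.0, s1_vote=1, s2_vote=0,
                          slope=0.0, iob=1.0)
        assert rec.b_final == 4.5
        assert rec.branch == Branch.HYPO_UP

    def test_nonnegative_under_random_inputs(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            rec = final_bolus(
                b_mod=rng.uniform(0, 12), mib=rng.uniform(0, 12),
                s1_vote=int(rng.integers(2)), s2_vote=int(rng.integers(2)),
                slope=rng.normal(), iob=rng.uniform(0, 8))
            assert rec.b_final >= 0.0


class TestClosedLoopPairing:
    def test_null_intervention_is_bit_exact(self):
        """alpha=gamma=1, af forced 0, no IOB: adjusted == standard dosing.

        Infinite sigmoid scales pin both logistic terms at exactly 0.5, so
        the adjustment factor is exactly zero; a sub-minute DIA zeroes IOB.
        """
        cfg = BolusConfig(alpha=1.0, gamma=1.0, s_g=float("inf"),
                          s_cf=float("inf"), dia_hours=0.01)
        scenario = SimScenario(n_patients=1, n_days=3, seed=4)
        patient = draw_patient("p", np.random.default_rng(6))
        real = realize_scenario(scenario, seed=8)
        always_event = make_adjusted_policy(lambda v: (1, 1), cfg)
        r_std = simulate_patient(patient, scenario, seed=0,
                                 policy=standard_policy, realization=real)
        r_adj = simulate_patient(patient, scenario, seed=0,
                                 policy=always_event, realization=real)
        np.testing.assert_array_equal(r_std.trace.values, r_adj.trace.values)
        assert [b.units for b in r_std.boluses] == \
               [b.units for b in r_adj.boluses]
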
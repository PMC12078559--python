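"""Two-state model: rate forms, Euler updates, conservation, regimes."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from azoswim.model import (
    CondensateState,
    ModelParams,
    Phase,
    SwitchingSchedule,
    ablation_compare,
    disassembly_ratio,
    disengagement_ratio,
    euler_step,
    frequency_sweep,
    load_default_params,
    simulate,
    summarize_run,
    DEFAULT_FREQUENCIES,
    DEFAULT_HORIZON,
)

E1 = -math.expm1(-1.0)  # 1 - 1/e


class TestRateForms:
    def test_zero_at_switch_instant(self, params):
        assert disassembly_ratio(0.0, params) == 0.0
        assert disengagement_ratio(0.0, params) == 0.0

    def test_saturation_limit(self, params):
        assert disassembly_ratio(1e6, params) == pytest.approx(params.A_max)
        assert disengagement_ratio(1e6, params) == pytest.approx(params.lambda_max)

    def test_closed_form_at_tau_star(self):
        p = ModelParams(A_max=0.05, lambda_max=0.8)
        assert disassembly_ratio(p.tau_star, p) == pytest.approx(0.05 * E1)
        assert disengagement_ratio(p.tau_star, p) == pytest.approx(0.8 * E1)

    def test_monotone_and_bounded(self, params):
        t = np.linspace(0, 10 * params.tau_star, 500)
        a = np.array([disassembly_ratio(x, params) for x in t])
        assert np.all(np.diff(a) >= 0)
        assert np.all(a <= params.A_max)

    def test_zero_lambda_max(self):
        p = ModelParams(lambda_max=0.0)
        assert disengagement_ratio(123.0, p) == 0.0

    def test_negative_lap_time_rejected(self, params):
        with pytest.raises(ValueError):
            disassembly_ratio(-0.1, params)
        with pytest.raises(ValueError):
            disengagement_ratio(-1e-9, params)


class TestParamValidation:
    @pytest.mark.parametrize("kwargs", [
        {"dt": 0.0}, {"dt": -1.0}, {"tau_star": 0.0},
        {"A_max": 150.0, "dt": 0.01},  # A_max*dt >= 1
        {"lambda_max": 1.5}, {"kappa": -0.1}, {"gamma": -1.0},
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs)

    def test_schedule_invariants(self):
        with pytest.raises(ValueError):
            SwitchingSchedule(interval_length=0.0)
        with pytest.raises(ValueError):
            SwitchingSchedule(interval_length=1.0, n_intervals=0)
        s = SwitchingSchedule(interval_length=4.0)
        assert s.switching_frequency * 2 * s.interval_length == pytest.approx(1.0)

    def test_yaml_profile_matches_dataclass_defaults(self):
        assert load_default_params() == ModelParams()


class TestEulerStep:
    def test_no_dynamics_only_clocks_advance(self):
        p = ModelParams(A_max=0.0, B=0.0, v_eject=0.0, v_reverse=0.0)
        s0 = CondensateState(m_L=80.0, m_D=5.0)
        s1 = euler_step(s0, p)
        assert s1.t == pytest.approx(p.dt)
        assert s1.t_lap == pytest.approx(p.dt)
        assert (s1.m_L, s1.m_D, s1.m_lost, s1.u, s1.x) == (80.0, 5.0, 0.0, 0.0, 0.0)

    def test_full_disengagement_blocks_dissociated_growth(self):
        # lambda -> 1 at t' >> tau*: Liquid still decays but nothing reaches m_D
        p = ModelParams(lambda_max=1.0)
        s0 = CondensateState(m_L=50.0, m_D=0.0, t_lap=100 * p.tau_star)
        s1 = euler_step(s0, p)
        assert s1.m_L < 50.0
        assert s1.m_D == pytest.approx(0.0, abs=1e-12)

    def test_hand_evaluated_uv_transfer(self):
        # constant-A limit via a constant ramp; lambda = 0
        p = ModelParams(A_max=0.2, lambda_max=0.0, ramp=lambda t, tau: 1.0)
        s0 = CondensateState(m_L=100.0, m_D=0.0)
        s1 = euler_step(s0, p)
        assert s1.m_L == pytest.approx(100.0 * (1 - 0.2 * p.dt))
        assert s1.m_D == pytest.approx(100.0 * 0.2 * p.dt)
        assert s1.m_lost == 0.0

    def test_vis_transfer_with_disengagement(self):
        p = ModelParams(B=0.5, kappa=0.2, v_reverse=0.0, v_eject=0.0)
        s0 = CondensateState(m_L=10.0, m_D=40.0, phase=Phase.VIS_TO_UV)
        s1 = euler_step(s0, p)
        dm = 0.5 * 40.0 * p.dt
        assert s1.m_D == pytest.approx(40.0 - dm)
        assert s1.m_L == pytest.approx(10.0 + 0.8 * dm)
        assert s1.m_lost == pytest.approx(0.2 * dm)

    def test_negative_mass_rejected(self):
        p = ModelParams(A_max=50.0, dt=0.019, ramp=lambda t, tau: 1.0)
        s0 = CondensateState(m_L=1.0)
        with pytest.raises(ValueError):
            euler_step(CondensateState(m_L=-1.0), p)


class TestSimulate:
    def test_initial_snapshot_is_initial_condition(self, params, short_schedule):
        series = simulate(params, short_schedule, m_L0=100.0)
        assert series.m_L[0] == 100.0
        assert series.m_D[0] == 0.0
        assert series.u[0] == 0.0 and series.x[0] == 0.0

    def test_geometric_decay_in_constant_A_limit(self):
        p = ModelParams(A_max=0.5, lambda_max=0.0, v_eject=0.0,
                        ramp=lambda t, tau: 1.0)
        sched = SwitchingSchedule(interval_length=1.0, n_intervals=1)
        series = simulate(p, sched, m_L0=100.0)
        n = np.arange(len(series))
        expected = 100.0 * (1 - 0.5 * p.dt) ** n
        np.testing.assert_allclose(series.m_L, expected, rtol=1e-12)

    def test_no_momentum_source_means_no_motion(self, short_schedule):
        p = ModelParams(v_eject=0.0, v_reverse=0.0)
        series = simulate(p, short_schedule)
        assert np.all(series.u == 0.0)
        assert np.all(series.x == 0.0)

    def test_phase_alternates_exactly_at_interval_multiples(self, params):
        sched = SwitchingSchedule(interval_length=1.0, n_intervals=4)
        series = simulate(params, sched)
        per = round(sched.interval_length / params.dt)
        # snapshot k reflects the phase governing the NEXT step
        assert list(series.phase[::per][:4]) == [0, 1, 0, 1]

    def test_timestamps_strictly_increasing_by_dt(self, params, short_schedule):
        series = simulate(params, short_schedule)
        np.testing.assert_allclose(np.diff(series.t), params.dt, rtol=1e-9)

    def test_non_commensurate_interval_rejected(self, params):
        with pytest.raises(ValueError, match="integer multiple"):
            simulate(params, SwitchingSchedule(interval_length=0.0153))

    def test_determinism_bit_identical(self, params, short_schedule):
        a = simulate(params, short_schedule)
        b = simulate(params, short_schedule)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.m_L, b.m_L)

    def test_mass_ledger_with_defaults(self, params):
        sched = SwitchingSchedule(interval_length=8.0, n_intervals=6)
        series = simulate(params, sched, m_L0=100.0)
        total = series.m_L + series.m_D + series.m_lost
        np.testing.assert_allclose(total, 100.0, rtol=1e-9)

    @settings(max_examples=25, deadline=None)
    @given(
        A_max=st.floats(0.0, 5.0),
        lambda_max=st.floats(0.0, 1.0),
        B=st.floats(0.0, 5.0),
        kappa=st.floats(0.0, 1.0),
        tau_star=st.floats(0.1, 20.0),
        v_eject=st.floats(0.0, 5.0),
        v_reverse=st.floats(0.0, 5.0),
        gamma=st.floats(0.0, 2.0),
        beta=st.floats(0.0, 2.0),
    )
    def test_ledger_and_positivity_property(self, A_max, lambda_max, B, kappa,
                                            tau_star, v_eject, v_reverse,
                                            gamma, beta):
        p = ModelParams(A_max=A_max, lambda_max=lambda_max, B=B, kappa=kappa,
                        tau_star=tau_star, dt=0.05, v_eject=v_eject,
                        v_reverse=v_reverse, gamma=gamma, beta=beta)
        sched = SwitchingSchedule(interval_length=1.0, n_intervals=4)
        series = simulate(p, sched, m_L0=100.0)
        np.testing.assert_allclose(series.m_L + series.m_D + series.m_lost,
                                   100.0, rtol=1e-9)
        assert np.all(series.m_L >= 0)
        assert np.all(series.m_D >= 0)


class TestSummariesAndSweeps:
    def test_constant_mass_gives_infinite_lifetime(self, short_schedule):
        p = ModelParams(A_max=0.0, B=0.0)
        summary = summarize_run(simulate(p, short_schedule))
        assert summary.lifetime == math.inf

    def test_zero_velocity_summary(self, short_schedule):
        p = ModelParams(v_eject=0.0, v_reverse=0.0)
        summary = summarize_run(simulate(p, short_schedule))
        assert summary.net_displacement == 0.0
        assert summary.positive_fraction == 0.0

    def test_lifetime_increases_with_frequency(self, params):
        lo, mid, hi = frequency_sweep(params, DEFAULT_FREQUENCIES, DEFAULT_HORIZON)
        assert lo.lifetime <= mid.lifetime <= hi.lifetime
        assert lo.lifetime < math.inf  # low f actually dies

    def test_direction_regimes(self, params):
        lo, mid, hi = frequency_sweep(params, DEFAULT_FREQUENCIES, DEFAULT_HORIZON)
        assert lo.net_displacement > 0
        assert lo.positive_fraction > 0.5
        assert mid.net_displacement < 0
        assert mid.peak_speed < lo.peak_speed
        assert abs(mid.net_displacement) > abs(lo.net_displacement)
        assert abs(hi.net_displacement) < abs(lo.net_displacement)
        assert abs(hi.net_displacement) < abs(mid.net_displacement)

    def test_sweep_needs_two_frequencies(self, params):
        with pytest.raises(ValueError):
            frequency_sweep(params, [0.05], 10.0)
        with pytest.raises(ValueError):
            frequency_sweep(params, [0.05, -0.1], 10.0)

    def test_ablation_removes_pull_regime(self, params):
        pair = ablation_compare(params, DEFAULT_FREQUENCIES, DEFAULT_HORIZON)
        for summary in pair["exchange_off"]:
            assert summary.net_displacement >= 0
        on = pair["exchange_on"]
        # sign inversion between low and intermediate f only with exchange on
        assert on[0].net_displacement > 0 > on[1].net_displacement
        # at low f the ablation does not flip the sign
        assert math.copysign(1, pair["exchange_off"][0].net_displacement) == \
            math.copysign(1, on[0].net_displacement)

    def test_ablation_without_ejection_is_static(self):
        p = ModelParams(exchange_enabled=False, v_eject=0.0)
        lo, hi = frequency_sweep(p, [0.025, 0.25], 40.0)
        assert lo.net_displacement == 0.0
        assert hi.net_displacement == 0.0
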
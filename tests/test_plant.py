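"""Muscle-fiber oculomotor plant: statics, scaling, equivalence, passivity."""

import numpy as np
import pytest

from sacgen.plant import (
    DEG,
    MONKEY_WHOLE_MUSCLE,
    PlantParams,
    PlantState,
    column_tension,
    default_plant,
    equilibrium_angle,
    fiber_parameter_scaling,
    initial_state,
    muscle_torques,
    plant_derivatives,
    saccade_metrics,
    simulate_plant,
)

WHOLE = default_plant()             # n=1, m=100 element-scaled canonical set
SMALL = default_plant(m=5)          # cheap variant for property checks


def aggregate_stiffness(p: PlantParams) -> float:
    """Independent series-spring oracle: 2 tendons + m fibers per column,
    n columns in parallel."""
    per_column = 1.0 / (2.0 / p.k_se + p.m / p.k_lt)
    return p.n * per_column


class TestColumnTension:
    def test_unloaded_rest_zero_tension(self):
        y = np.zeros(SMALL.m + 2)
        f = np.zeros(SMALL.m)
        assert column_tension(y, 0.0, f, SMALL) == 0.0

    def test_static_state_recovers_assumed_tension(self):
        """Static per-element solution built for tension T returns T."""
        p = SMALL
        t0, f0 = 0.37, 0.6
        y = np.empty(p.m + 2)
        y[0] = y[-1] = -t0 / p.k_se
        y[1:-1] = (f0 - t0) / p.k_lt
        assert column_tension(y, 0.0, np.full(p.m, f0), p) == pytest.approx(t0)

    def test_m1_reduces_to_voigt_plus_tendon(self):
        """m=1: hand-solved single fiber + two tendons closed form."""
        p = fiber_parameter_scaling(MONKEY_WHOLE_MUSCLE, 1, 1)
        y = np.array([0.1e-3, -0.2e-3, 0.05e-3])
        f = np.array([0.5])
        xdot = 1e-3
        denom = 2.0 / p.b_2 + 1.0 / p.b_1
        num = -p.k_se * (y[0] + y[2]) / p.b_2 + (f[0] - p.k_lt * y[1]) / p.b_1
        assert column_tension(y, xdot, f, p) == pytest.approx((num - xdot) / denom)

    def test_series_constraint_satisfied(self):
        """With T_i resolved, the element stretch-rates sum to xdot."""
        rng = np.random.default_rng(11)
        p = SMALL
        st = PlantState(0.0, 0.5, rng.normal(0, 1e-3, (2, p.m + 2)))
        f = rng.uniform(0, 1, (1, p.m))
        _, _, dy = plant_derivatives(st, (f, f), p)
        xdot = p.r * st.omega
        assert dy[0].sum() == pytest.approx(xdot, abs=1e-12)
        assert dy[1].sum() == pytest.approx(xdot, abs=1e-12)


class TestTorquesAndDerivatives:
    def test_symmetric_state_no_net_drive(self):
        st = initial_state(WHOLE, 0.0, 0.4, 0.4)
        t_ag, t_ant = muscle_torques(st, (0.004 * np.ones(100), 0.004 * np.ones(100)), WHOLE)
        assert t_ag == pytest.approx(t_ant, rel=1e-12)
        _, domega, _ = plant_derivatives(st, (0.004 * np.ones(100),) * 2, WHOLE)
        assert domega == pytest.approx(0.0, abs=1e-9)

    def test_equilibrium_state_is_stationary(self):
        f_ag, f_ant = 0.55, 0.25
        st = initial_state(WHOLE, equilibrium_angle(f_ag, f_ant, WHOLE), f_ag, f_ant)
        # per-fiber tension = whole-muscle tension / n (n=1 here), uniform
        dth, dom, dy = plant_derivatives(st, (f_ag, f_ant), WHOLE)
        assert abs(dom) < 1e-6
        assert np.max(np.abs(dy)) < 1e-12

    def test_agonist_step_accelerates_eye_positively(self):
        st = initial_state(WHOLE, 0.0, 0.4, 0.4)
        _, dom, _ = plant_derivatives(st, (0.8, 0.4), WHOLE)
        assert dom > 0

    def test_torque_sum_equals_column_tensions_static(self):
        """Eq for T_ag via K_se y_1 + B_2 ydot_1 equals sum of T_i."""
        st = initial_state(WHOLE, 4.0, 0.6, 0.3)
        t_ag, t_ant = muscle_torques(st, (0.6, 0.3), WHOLE)
        p = WHOLE
        ti_ag = column_tension(st.y[0], p.r * st.omega, np.full(p.m, 0.6), p, "agonist")
        _, _, dy = plant_derivatives(st, (0.6, 0.3), p)
        lhs = -(p.k_se * st.y[0, 0] + p.b_2 * dy[0, 0])
        assert lhs == pytest.approx(ti_ag, rel=1e-9)
        assert t_ag == pytest.approx(ti_ag, rel=1e-9)


class TestScaling:
    def test_aggregate_stiffness_preserved(self):
        whole = aggregate_stiffness(fiber_parameter_scaling(MONKEY_WHOLE_MUSCLE, 1, 1))
        for n, m in [(1, 1), (1, 100), (2, 50), (4, 10)]:
            p = fiber_parameter_scaling(MONKEY_WHOLE_MUSCLE, n, m)
            assert aggregate_stiffness(p) == pytest.approx(whole, rel=1e-9)
            assert p.k_lt_muscle == pytest.approx(MONKEY_WHOLE_MUSCLE.k_lt, rel=1e-12)

    def test_doubling_m_leaves_aggregate_unchanged(self):
        p1 = fiber_parameter_scaling(MONKEY_WHOLE_MUSCLE, 1, 50)
        p2 = fiber_parameter_scaling(MONKEY_WHOLE_MUSCLE, 1, 100)
        assert aggregate_stiffness(p1) == pytest.approx(aggregate_stiffness(p2), rel=1e-12)


class TestSimulation:
    def test_frozen_fixation_forcing_holds_position(self):
        f_ag, f_ant = 0.55, 0.25
        theta0 = equilibrium_angle(f_ag, f_ant, WHOLE)
        t, theta, omega = simulate_plant(
            lambda t_ms: (f_ag, f_ant), WHOLE, duration=60.0, dt=0.02,
            theta0_deg=theta0, f_fix=(f_ag, f_ant))
        assert np.max(np.abs(theta - theta0)) < 1e-6
        assert np.max(np.abs(omega)) < 1e-4

    def test_steady_state_matches_equilibrium_closed_form(self):
        """Simulated settle point equals theta_ss from the static balance."""
        f_ag, f_ant = 0.62, 0.22
        t, theta, omega = simulate_plant(
            lambda t_ms: (f_ag, f_ant), WHOLE, duration=500.0, dt=0.05,
            theta0_deg=0.0, f_fix=(0.4, 0.4))
        expected = equilibrium_angle(f_ag, f_ant, WHOLE)
        assert theta[-1] == pytest.approx(expected, abs=1e-3)
        # and the realized muscle forces satisfy Eq of motion statics
        st = initial_state(WHOLE, theta[-1], f_ag, f_ant)
        t_ag, t_ant = muscle_torques(st, (f_ag, f_ant), WHOLE)
        assert theta[-1] * DEG == pytest.approx(
            (t_ag - t_ant) / (WHOLE.k_p * WHOLE.r), rel=1e-6)

    def test_whole_muscle_equivalence(self):
        """m=100 fiber chain matches the m=1 reduction on identical forcing."""
        def forcing(t_ms):
            pulse = 0.9 if 10.0 <= t_ms < 50.0 else 0.4
            return pulse, max(0.4 - 0.006 * min(t_ms, 50.0), 0.05)

        results = {}
        for m in (1, 100):
            p = default_plant(m=m)
            t, theta, _ = simulate_plant(forcing, p, duration=120.0, dt=0.02,
                                         theta0_deg=0.0, f_fix=(0.4, 0.4))
            results[m] = theta
        rms = np.sqrt(np.mean((results[1] - results[100]) ** 2))
        scale = np.max(np.abs(results[100]))
        assert rms <= 0.01 * scale

    def test_passivity_decay_without_active_tension(self):
        """All F = 0: a displaced eye relaxes toward primary position."""
        st0 = initial_state(WHOLE, 8.0, 0.0, 0.0)
        t, theta, _ = simulate_plant(lambda t_ms: (0.0, 0.0), WHOLE,
                                     duration=400.0, dt=0.05, state0=st0)
        assert abs(theta[-1]) < 0.1 * abs(theta[0])
        assert np.max(np.abs(theta)) <= abs(theta[0]) + 1e-6


class TestMetrics:
    def test_metrics_on_synthetic_trajectory(self):
        t = np.arange(0, 100, 0.1)
        theta = 10.0 / (1 + np.exp(-(t - 50) / 5.0))
        omega = np.gradient(theta, t) * 1e3
        m = saccade_metrics(t, theta, omega)
        assert m.peak_velocity_deg_s == pytest.approx(500.0, rel=0.05)
        # |v| > 10 deg/s for the sigmoid: 500/cosh^2((t-50)/10) > 10
        assert m.onset_ms == pytest.approx(50 - 10 * np.arccosh(np.sqrt(50)), abs=0.5)
        assert m.duration_ms == pytest.approx(20 * np.arccosh(np.sqrt(50)), abs=1.0)
        assert m.magnitude_deg == pytest.approx(10.0, abs=0.5)
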
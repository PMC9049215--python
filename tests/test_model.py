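"""Unit and property tests for the hybrid dynamics core."""
from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings
from hypothesis import strategies as st

from spinegait import ModelParameters, SolverSettings, simulate
from spinegait.model import (ContinuousState, CrashError, HybridState,
                             LegMode, LegState, NoContactError,
                             dynamics_rhs, generalized_forces, hip_position,
                             leg_angle, leg_length, leg_length_gradient,
                             mass_matrix, total_energy, touchdown_value,
                             liftoff_value)


def _flight_state(q, qdot, g1=0.3, g2=0.3, t=0.0):
    return HybridState(ContinuousState(np.asarray(q, float),
                                       np.asarray(qdot, float), t=t),
                       (LegState(1, LegMode.AIR, g1),
                        LegState(2, LegMode.AIR, g2)))


def _stance_leg(index, q, p, gamma=0.0):
    """Place the toe so the leg has angle ``gamma`` from the vertical."""
    hx, hy = hip_position(q, index, p)
    return LegState(index, LegMode.STANCE, gamma_td=gamma,
                    toe_x=hx + hy * math.tan(gamma))


# --------------------------------------------------------------------- #
# mass matrix

class TestMassMatrix:
    def test_straight_spine(self, params):
        M = mass_matrix(np.array([0.0, 0.69, 0.0, 0.0]), params)
        assert np.allclose(np.diag(M), [38.0, 38.0, 4.2558, 1.06])
        assert np.allclose(M, M.T)

    def test_right_angle_swaps_rotational_entries(self, params):
        M = mass_matrix(np.array([0.0, 0.69, 0.0, math.pi / 2]), params)
        assert np.allclose(np.diag(M), [38.0, 38.0, 1.06, 4.2558])

    @given(phi=st.floats(-math.pi, math.pi, allow_nan=False))
    @hyp_settings(deadline=None, max_examples=50)
    def test_trace_identity_and_positive_definite(self, phi):
        p = ModelParameters()
        M = mass_matrix(np.array([0.0, 0.7, 0.1, phi]), p)
        # cos^2 + sin^2 = 1 makes the two rotational entries sum constant
        expected = 4.0 * p.J + 2.0 * p.m * p.r ** 2
        assert np.isclose(M[2, 2] + M[3, 3], expected)
        assert np.all(np.linalg.eigvalsh(M) > 0)


# --------------------------------------------------------------------- #
# leg geometry

class TestLegGeometry:
    def test_vertical_leg_at_nominal_length(self, params):
        q = np.array([0.0, 0.69, 0.0, 0.0])
        hx, hy = hip_position(q, 2, params)
        leg = LegState(2, LegMode.STANCE, gamma_td=0.0, toe_x=hx)
        assert hy == pytest.approx(0.69)
        assert leg_length(q, leg, params) == pytest.approx(0.69)
        assert leg_angle(q, leg, params) == pytest.approx(0.0)

    def test_vertical_distance_when_compressed(self, params):
        q = np.array([0.0, 0.6 - params.hip_offset * 1.0, 0.0, 0.0])
        # theta = phi = 0: hip height is y + sign*(r+d)*0, so place y at 0.6
        q = np.array([0.0, 0.6, 0.0, 0.0])
        hx, hy = hip_position(q, 1, params)
        leg = LegState(1, LegMode.STANCE, toe_x=hx)
        assert leg_length(q, leg, params) == pytest.approx(0.6)

    def test_air_leg_has_nominal_length(self, params):
        q = np.array([0.0, 1.0, 0.2, -0.1])
        leg = LegState(1, LegMode.AIR, gamma_td=0.25)
        assert leg_length(q, leg, params) == params.l0

    def test_length_matches_brute_force_hip_geometry(self, params, rng):
        # independent reconstruction: body COMs at +-r cos/sin(theta)cos(phi)
        # from the whole-body COM, hips d beyond them along each body axis
        for _ in range(25):
            x, y = rng.normal(0, 1), rng.uniform(0.4, 0.9)
            th, ph = rng.uniform(-0.5, 0.5, 2)
            toe = rng.normal(0, 0.5)
            q = np.array([x, y, th, ph])
            for index, s in ((1, -1.0), (2, 1.0)):
                c = np.array([x + s * params.r * math.cos(th) * math.cos(ph),
                              y + s * params.r * math.sin(th) * math.cos(ph)])
                psi = th + s * ph
                hip = c + s * params.d * np.array([math.cos(psi),
                                                   math.sin(psi)])
                expected = math.hypot(hip[0] - toe, hip[1])
                leg = LegState(index, LegMode.STANCE, toe_x=toe)
                assert leg_length(q, leg, params) == pytest.approx(
                    expected, abs=1e-12)

    def test_length_gradient_matches_finite_differences(self, params, rng):
        for _ in range(10):
            q = np.array([rng.normal(), rng.uniform(0.5, 0.8),
                          rng.uniform(-0.4, 0.4), rng.uniform(-0.4, 0.4)])
            leg = LegState(1, LegMode.STANCE, toe_x=rng.normal(0, 0.3))
            grad = leg_length_gradient(q, leg, params)
            for j in range(4):
                dq = np.zeros(4)
                dq[j] = 1e-7
                fd = (leg_length(q + dq, leg, params)
                      - leg_length(q - dq, leg, params)) / 2e-7
                assert grad[j] == pytest.approx(fd, abs=1e-7)


# --------------------------------------------------------------------- #
# forces and accelerations

class TestForces:
    def test_flight_at_rest_gravity_only(self, params):
        q = np.array([0.0, 1.0, 0.0, 0.0])
        legs = (LegState(1), LegState(2))
        h, v = generalized_forces(q, np.zeros(4), legs, params)
        assert np.allclose(h, 0.0)
        assert np.allclose(v, [0.0, 2 * params.m * params.g, 0.0, 0.0])

    def test_spine_spring_torque(self, params):
        q = np.array([0.0, 1.0, 0.0, 0.2])
        _, v = generalized_forces(q, np.zeros(4), (LegState(1), LegState(2)),
                                  params)
        assert v[3] == pytest.approx(4.0 * params.kt * 0.2)  # 80 N m

    def test_unloaded_stance_leg_contributes_nothing(self, params):
        q = np.array([0.0, 0.69, 0.0, 0.0])
        legs_air = (LegState(1), LegState(2))
        hx, _ = hip_position(q, 2, params)
        legs = (LegState(1), LegState(2, LegMode.STANCE, toe_x=hx))
        _, v_air = generalized_forces(q, np.zeros(4), legs_air, params)
        _, v = generalized_forces(q, np.zeros(4), legs, params)
        assert np.allclose(v, v_air, atol=1e-10)

    def test_free_fall(self, params):
        st = _flight_state([0, 1.0, 0, 0], [0, 0, 0, 0])
        qdd = dynamics_rhs(st, params)
        assert np.allclose(qdd, [0.0, -params.g, 0.0, 0.0])

    def test_flight_com_decouples(self, params, rng):
        for _ in range(10):
            st = _flight_state(
                [rng.normal(), rng.uniform(0.5, 1.2),
                 rng.uniform(-0.5, 0.5), rng.uniform(-0.5, 0.5)],
                rng.normal(0, 2, 4))
            qdd = dynamics_rhs(st, params)
            assert qdd[0] == pytest.approx(0.0, abs=1e-12)
            assert qdd[1] == pytest.approx(-params.g, abs=1e-12)

    def test_rhs_matches_lagrangian_oracle(self, params, rng):
        """Finite-difference Euler-Lagrange from independently written
        energy functions reproduces the closed-form accelerations."""
        from oracles import lagrangian_accelerations, random_hybrid_states
        for st in random_hybrid_states(params, rng, 30):
            qdd = dynamics_rhs(st, params)
            expected = lagrangian_accelerations(st.cont.q, st.cont.qdot,
                                                st.legs, params)
            assert np.allclose(qdd, expected, rtol=1e-6, atol=1e-6)


# --------------------------------------------------------------------- #
# energy

class TestEnergy:
    def test_potential_only(self, params):
        st = _flight_state([0, 1.0, 0, 0], [0, 0, 0, 0])
        assert total_energy(st, params) == pytest.approx(
            2 * params.m * params.g, abs=1e-9)  # 372.78 J at y = 1 m

    def test_stance_at_nominal_length_equals_flight_expression(self, params):
        q = np.array([0.3, 0.69, 0.0, 0.0])
        qd = np.array([5.0, -0.2, 0.4, 0.0])
        flight = _flight_state(q, qd)
        hx, _ = hip_position(q, 2, params)
        stance = HybridState(ContinuousState(q, qd),
                             (LegState(1), LegState(2, LegMode.STANCE,
                                                    toe_x=hx)))
        assert total_energy(stance, params) == pytest.approx(
            total_energy(flight, params), abs=1e-12)


# --------------------------------------------------------------------- #
# guards

class TestGuards:
    def test_touchdown_zero_at_contact_height(self, params):
        gamma = 0.25
        # place the hip exactly at l0*cos(gamma): guard vanishes
        y = params.l0 * math.cos(gamma)
        q = np.array([0.0, y, 0.0, 0.0])
        st = _flight_state(q, np.zeros(4), g1=gamma)
        assert touchdown_value(st, st.legs[0], params) == pytest.approx(
            0.0, abs=1e-12)

    def test_liftoff_zero_at_nominal_length(self, params):
        q = np.array([0.0, 0.69, 0.0, 0.0])
        hx, _ = hip_position(q, 1, params)
        leg = LegState(1, LegMode.STANCE, toe_x=hx)
        st = HybridState(ContinuousState(q, np.zeros(4)),
                         (leg, LegState(2)))
        assert liftoff_value(st, leg, params) == pytest.approx(0.0, abs=1e-12)
        # compression gives a positive guard value (no event yet)
        q2 = np.array([0.0, 0.60, 0.0, 0.0])
        st2 = HybridState(ContinuousState(q2, np.zeros(4)),
                          (LegState(1, LegMode.STANCE, toe_x=hx),
                           LegState(2)))
        assert liftoff_value(st2, st2.legs[0], params) > 0


# --------------------------------------------------------------------- #
# event-driven integration

class TestSimulate:
    def test_ballistic_flight(self, params, settings):
        st = _flight_state([0, 2.0, 0, 0], [5.0, 1.0, 0, 0], g1=0.0, g2=0.0)
        traj = simulate(st, params, stop=("time", 0.2), settings=settings)
        df = traj.sample(51)
        # x linear in t; y a parabola; apex height from the closed form
        assert np.allclose(df["x"], 5.0 * df["t"], atol=1e-9)
        y_apex = 2.0 + 1.0 ** 2 / (2 * params.g)
        t_apex = 1.0 / params.g
        assert traj.state_at(t_apex).cont.q[1] == pytest.approx(
            y_apex, abs=1e-9)
        assert df["y"].max() <= y_apex + 1e-9

    def test_flight_theta_momentum_constant(self, params, settings):
        st = _flight_state([0, 2.0, 0.1, 0.2], [5.0, 0.5, 1.0, 3.0])
        traj = simulate(st, params, stop=("time", 0.15), settings=settings)
        df = traj.sample(101)
        mom = ((2 * params.J + 2 * params.m * params.r ** 2
                * np.cos(df["phi"]) ** 2) * df["thetadot"])
        assert np.ptp(mom) < 1e-8 * abs(mom.iloc[0])

    def test_touchdown_flips_mode_and_anchors_toe(self, params, settings):
        gamma = 0.2
        st = _flight_state([0, 0.75, 0, 0.05], [8.0, 0.0, 0, 0],
                           g1=1.2, g2=gamma)
        traj = simulate(st, params, stop=("time", 0.2), settings=settings)
        tds = [e for e in traj.events if e.kind == "touchdown2"]
        assert len(tds) == 1
        leg = tds[0].state.legs[1]
        assert leg.mode is LegMode.STANCE
        hx, hy = hip_position(tds[0].state.cont.q, 2, params)
        assert leg.toe_x == pytest.approx(
            hx + params.l0 * math.sin(gamma), abs=1e-9)
        # the anchor never moves within the stance
        stances = traj.stance_intervals(2)
        assert stances and all(
            abs(l.toe_x - leg.toe_x) < 1e-12 for (_, _, l) in stances)

    def test_stance_has_positive_duration_and_nominal_ends(self, params,
                                                           settings):
        st = _flight_state([0, 0.75, 0, 0.05], [8.0, 0.0, 0, 0],
                           g1=1.2, g2=0.2)
        traj = simulate(st, params, stop=("time", 0.2), settings=settings)
        (t0, t1, leg) = traj.stance_intervals(2)[0]
        assert t1 - t0 > 1e-4
        for t in (t0, t1):
            l = leg_length(traj.state_at(t).cont.q, leg, params)
            assert l == pytest.approx(params.l0, abs=1e-8)
        # liftoff resets the leg angle to the touchdown angle
        after = traj.state_at(t1 + 1e-6).legs[1]
        assert after.mode is LegMode.AIR and after.gamma_td == 0.2

    def test_no_contact_failure(self, params):
        st = _flight_state([0, 2.0, 0, 0], [5.0, 0, 0, 0], g1=0.1, g2=0.1)
        with pytest.raises(NoContactError):
            simulate(st, params, stop="cycle",
                     settings=SolverSettings(horizon=0.05))

    def test_crash_failure(self, params, settings):
        # touchdown angles so oblique that the toe never reaches ground
        st = _flight_state([0, 0.8, 0, 0], [2.0, 0, 0, 0], g1=1.5, g2=1.5)
        with pytest.raises(CrashError):
            simulate(st, params, stop="cycle", settings=settings)

    def test_energy_conserved_across_events(self, params, settings):
        st = _flight_state([0, 0.75, 0, 0.05], [8.0, 0.0, 0, 0],
                           g1=1.2, g2=0.2)
        traj = simulate(st, params, stop=("time", 0.2), settings=settings)
        assert traj.energy_drift(101) < 1e-8
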
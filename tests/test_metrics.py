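"""Tests for gait classification, fluctuations and impulse metrics."""
from __future__ import annotations

import math

import numpy as np
import pytest

from spinegait import ModelParameters, SolverSettings, simulate
from spinegait.metrics import (GaitCharacteristics, classify_branch,
                               classify_type, compare_to_reference,
                               average_velocity, fluctuations, impulses,
                               impulses_augmented, torque_decomposition)
from spinegait.model import (ContinuousState, HybridState, LegMode, LegState,
                             generalized_forces)
from spinegait.reference import CHEETAH_REFERENCE


def _ballistic(params, settings, qdot=(6.0, 1.0, 0.8, 0.0), T=0.15):
    st = HybridState(
        ContinuousState(np.array([0.0, 1.0, 0.0, 0.0]),
                        np.array(qdot, dtype=float)),
        (LegState(1, LegMode.AIR, 0.0), LegState(2, LegMode.AIR, 0.0)))
    return simulate(st, params, stop=("time", T), settings=settings)


class TestClassification:
    def test_featured_solutions(self, branch1_solution, branch2_solution):
        """At thetadot* = -1.5, y* = 0.69: the spring-aided gait is the
        cheetah-like extended-then-gathered type; the spring-opposing
        one is its reversed-flight counterpart."""
        assert branch1_solution.gait_type == "EG"
        assert branch1_solution.branch == 1
        assert branch2_solution.gait_type == "GE"
        assert branch2_solution.branch == 2

    def test_two_flights_without_double_stance(self, branch1_solution):
        phases = [lab for (_, _, lab, _) in
                  branch1_solution.trajectory.phases()]
        assert "double_stance" not in phases
        assert phases.count("single_stance") == 2

    def test_branch_label_sampling_invariance(self, branch1_solution,
                                              branch2_solution, params):
        for sol in (branch1_solution, branch2_solution):
            assert classify_branch(sol.trajectory, params) == sol.branch

    def test_spring_torque_sign_distinguishes_branches(self, branch1_solution,
                                                       branch2_solution,
                                                       params):
        """Branch 1 keeps the spine flexed (phi < 0) through stance so
        the spring torque extends the joint; branch 2 the reverse."""
        for sol, sign in ((branch1_solution, 1.0), (branch2_solution, -1.0)):
            td = torque_decomposition(sol.trajectory, params)
            in_stance = (np.abs(td.tau_1) > 1e-9) | (np.abs(td.tau_2) > 1e-9)
            assert sign * td.tau_t[in_stance].mean() > 0


class TestFluctuations:
    def test_ballistic_channels(self, params, settings):
        traj = _ballistic(params, settings)
        chars = fluctuations(traj, n=4001)
        # flight: y is a parabola, theta linear, phi follows the
        # conservative spine oscillation
        y_apex = 1.0 + 1.0 ** 2 / (2 * params.g)
        y_end = 1.0 + 1.0 * 0.15 - 0.5 * params.g * 0.15 ** 2
        assert chars.delta_y == pytest.approx(y_apex - min(1.0, y_end),
                                              rel=1e-6)
        # with a straight, non-rotating spine the pitch rate is constant
        assert chars.delta_theta == pytest.approx(0.8 * 0.15, rel=1e-6)
        assert chars.delta_phi == pytest.approx(0.0, abs=1e-12)

    def test_negative_fluctuation_rejected(self):
        with pytest.raises(ValueError):
            GaitCharacteristics(-0.1, 0.0, 0.0)


class TestVelocity:
    def test_ballistic_average_equals_constant_xdot(self, params, settings):
        traj = _ballistic(params, settings)
        assert average_velocity(traj) == pytest.approx(6.0, abs=1e-10)

    def test_cycle_average_equals_time_integral(self, branch1_solution):
        traj = branch1_solution.trajectory
        df = traj.sample(20001)
        integral = np.trapezoid(df["xdot"], df["t"]) / traj.duration
        assert average_velocity(traj) == pytest.approx(integral, rel=1e-7)


class TestImpulses:
    def test_flight_only_zero(self, params, settings):
        traj = _ballistic(params, settings)
        perf = impulses(traj, params)
        assert perf.p_net == perf.p_y == 0.0
        assert perf.p1x_neg == perf.p1x_pos == 0.0

    def test_vertical_impulse_balances_weight(self, branch1_solution,
                                              branch2_solution, params):
        """Per-leg vertical impulse m g T: each leg carries half the
        weight impulse of the 2m body over a periodic cycle."""
        for sol in (branch1_solution, branch2_solution):
            perf = impulses(sol.trajectory, params)
            expected = params.m * params.g * sol.period
            assert perf.p_y == pytest.approx(expected, rel=1e-6)

    def test_horizontal_impulses_close(self, branch1_solution, params):
        perf = impulses(branch1_solution.trajectory, params)
        total = perf.p1x_neg + perf.p1x_pos + perf.p2x_neg + perf.p2x_pos
        scale = abs(perf.p1x_pos) + abs(perf.p1x_neg)
        assert abs(total) < 1e-6 * scale
        assert perf.p2x_pos == pytest.approx(-perf.p1x_neg, rel=1e-5)
        assert perf.p2x_neg == pytest.approx(-perf.p1x_pos, rel=1e-5)

    def test_quadrature_matches_augmented_state_oracle(self, branch1_solution,
                                                       params):
        a = impulses(branch1_solution.trajectory, params)
        b = impulses_augmented(branch1_solution.trajectory, params)
        for name in ("p_net", "p1x_neg", "p1x_pos", "p2x_neg", "p2x_pos",
                     "p_y"):
            va, vb = getattr(a, name), getattr(b, name)
            assert va == pytest.approx(vb, rel=1e-8, abs=1e-8), name


class TestTorque:
    def test_flight_leg_moments_vanish(self, params, settings):
        td = torque_decomposition(_ballistic(params, settings), params)
        assert np.all(td.tau_1 == 0.0) and np.all(td.tau_2 == 0.0)

    def test_decomposition_sums_to_potential_row(self, branch1_solution,
                                                 params):
        """tau_t + tau_1 + tau_2 equals the full (negated) phi row of
        the potential gradient along the cycle."""
        traj = branch1_solution.trajectory
        td = torque_decomposition(traj, params, n=201)
        for i, t in enumerate(td.t):
            st = traj.state_at(t)
            _, v = generalized_forces(st.cont.q, st.cont.qdot, st.legs,
                                      params)
            total = td.tau_t[i] + td.tau_1[i] + td.tau_2[i]
            assert total == pytest.approx(-v[3], abs=1e-8)

    def test_straight_spine_no_spring_torque(self, branch1_solution, params):
        td = torque_decomposition(branch1_solution.trajectory, params)
        # tau_t = -4 kt phi: vanishes exactly where phi does
        i = int(np.argmin(np.abs(td.tau_t)))
        phi = branch1_solution.trajectory.state_at(td.t[i]).cont.q[3]
        assert td.tau_t[i] == pytest.approx(-4 * params.kt * phi, abs=1e-12)


class TestReferenceComparison:
    def test_zero_scores_at_the_means(self):
        chars = GaitCharacteristics(0.057, 0.20, 0.47)
        out = compare_to_reference(chars, CHEETAH_REFERENCE)
        for rec in out.values():
            assert rec["score"] == pytest.approx(0.0, abs=1e-12)
            assert rec["within_se"]

    def test_scores_are_standardized(self):
        chars = GaitCharacteristics(0.057 + 0.012, 0.20, 0.47)
        out = compare_to_reference(chars, CHEETAH_REFERENCE)
        assert out["delta_y"]["score"] == pytest.approx(1.0)

    def test_zero_se_rejected(self):
        chars = GaitCharacteristics(0.05, 0.2, 0.4)
        with pytest.raises(ZeroDivisionError):
            compare_to_reference(chars, {"delta_y": (0.057, 0.0),
                                         "delta_theta": (0.2, 0.1),
                                         "delta_phi": (0.4, 0.1)})
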
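"""Gait classification and performance metrics for periodic cycles.

Works on one apex-to-apex cycle of the hybrid model.  Covers the
six-type flight/double-stance classification, the branch label from the
direction of the spine-spring torque in stance, the three fluctuation
characteristics (COM height, whole-body pitch, spine half angle), the
average horizontal velocity, and the ground-reaction-force impulses.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import simpson, solve_ivp
from scipy.optimize import brentq

from .model import (HybridState, LegMode, LegState, Trajectory,
                    hip_position, leg_angle, leg_length)
from .params import ModelParameters

__all__ = [
    "GaitCharacteristics", "PerformanceMetrics", "TorqueDecomposition",
    "AmbiguousFlightError", "IndeterminateBranchError",
    "classify_type", "classify_branch", "stance_spring_alignment",
    "fluctuations", "average_velocity", "impulses", "torque_decomposition",
    "compare_to_reference",
]

logger = logging.getLogger(__name__)


class AmbiguousFlightError(RuntimeError):
    """Spine exactly straight at a mid-flight instant; type undefined."""


class IndeterminateBranchError(RuntimeError):
    """Stance-averaged spine-spring torque is numerically zero."""


@dataclass(frozen=True)
class GaitCharacteristics:
    """Cycle fluctuations: max - min of the COM height (m), whole-body
    pitch (rad) and spine half angle (rad)."""

    delta_y: float
    delta_theta: float
    delta_phi: float

    def __post_init__(self) -> None:
        if min(self.delta_y, self.delta_theta, self.delta_phi) < 0:
            raise ValueError("fluctuations must be non-negative")


@dataclass(frozen=True)
class PerformanceMetrics:
    """Velocity and per-leg impulse summary of one cycle.

    Sign conventions follow the leg-angle convention: ``p1x_neg`` is the
    braking (negative) horizontal impulse of leg 1 accumulated while its
    leg angle is positive, ``p1x_pos`` the propulsive part after the leg
    passes the vertical; ``p_y`` is the (positive) vertical impulse per
    leg and ``p_net`` the net axial spring impulse per leg."""

    v_bar: float
    p_net: float
    p1x_neg: float
    p1x_pos: float
    p2x_neg: float
    p2x_pos: float
    p_y: float


@dataclass(frozen=True)
class TorqueDecomposition:
    """Torques on the spine coordinate phi, positive = extension.

    ``tau_t`` is the spine-spring torque ``-4 kt phi``; ``tau_1`` and
    ``tau_2`` are the moments of the two leg ground-reaction forces,
    zero whenever the leg is in the air."""

    t: np.ndarray
    tau_t: np.ndarray
    tau_1: np.ndarray
    tau_2: np.ndarray


# --------------------------------------------------------------------- #
# helpers

def _foreleg_index(traj: Trajectory) -> int:
    """Leg whose hip leads in the direction of travel at the cycle start."""
    st = traj.initial_state()
    q = st.cont.q
    direction = 1.0 if st.cont.qdot[0] >= 0 else -1.0
    hx1, _ = hip_position(q, 1, traj.params)
    hx2, _ = hip_position(q, 2, traj.params)
    return 2 if (hx2 - hx1) * direction > 0 else 1


def _flight_windows(traj: Trajectory) -> list[list[tuple[float, float]]]:
    """Flight phases of the cycle; the first and last windows (the cycle
    starts and ends mid-flight at the apex) are merged into one wrapped
    flight, listed first."""
    phases = traj.phases()
    flights = [(t0, t1) for (t0, t1, label, _) in phases if label == "flight"]
    if not flights:
        return []
    wraps_start = abs(flights[0][0] - traj.t0) < 1e-12
    wraps_end = abs(flights[-1][1] - traj.t1) < 1e-12
    if len(flights) >= 2 and wraps_start and wraps_end:
        wrapped = [flights[-1], flights[0]]
        middle = [[f] for f in flights[1:-1]]
        return [wrapped] + middle
    return [[f] for f in flights]


def _flight_midpoint_phi(traj: Trajectory,
                         windows: list[tuple[float, float]],
                         where: str = "midpoint") -> float:
    """Spine half angle at the representative instant of a flight phase.

    ``where="midpoint"`` uses the temporal midpoint (wrap-aware);
    ``where="apex"`` uses the instant of maximum COM height."""
    durations = [t1 - t0 for (t0, t1) in windows]
    total = sum(durations)
    if where == "apex":
        best_t, best_y = None, -np.inf
        for (t0, t1) in windows:
            for t in np.linspace(t0, t1, 101):
                y = traj.state_at(t).cont.q[1]
                if y > best_y:
                    best_t, best_y = t, y
        tm = best_t
    else:
        offset = 0.5 * total
        tm = None
        for (t0, t1), dur in zip(windows, durations):
            if offset <= dur + 1e-15:
                tm = t0 + offset
                break
            offset -= dur
        assert tm is not None
    return float(traj.state_at(tm).cont.q[3])


def classify_type(traj: Trajectory, mid_flight: str = "midpoint") -> str:
    """Six-type gait label of one apex-to-apex cycle.

    Single-flight cycles with a double-stance phase are ``E`` (spine
    extended, ``phi > 0``, at mid flight) or ``G`` (flexed).  Two-flight
    cycles without double stance get two letters, ordered from the
    flight that precedes the foreleg touchdown: ``EE``, ``GG``, ``EG``,
    ``GE``.
    """
    flights = _flight_windows(traj)
    has_double = any(label == "double_stance" for (_, _, label, _)
                     in traj.phases())
    labels = []
    for windows in flights:
        phi_mid = _flight_midpoint_phi(traj, windows, mid_flight)
        if phi_mid == 0.0:
            raise AmbiguousFlightError("phi = 0 exactly at mid flight")
        labels.append("E" if phi_mid > 0 else "G")
    if len(labels) == 1:
        if not has_double:
            logger.warning("single flight without double stance")
        return labels[0]
    if len(labels) != 2:
        raise ValueError(f"unexpected flight count {len(labels)}")
    # order from the flight preceding the foreleg touchdown: the wrapped
    # flight (index 0) contains the cycle-start apex, so it precedes the
    # first touchdown of the cycle
    fore = _foreleg_index(traj)
    first_td = min((e for e in traj.events if e.kind.startswith("touchdown")),
                   key=lambda e: e.t)
    if first_td.kind == f"touchdown{fore}":
        return labels[0] + labels[1]
    return labels[1] + labels[0]


def stance_spring_alignment(traj: Trajectory,
                            p: ModelParameters | None = None) -> float:
    """Stance-time-averaged spine-spring torque ``-4 kt phi`` (N m).

    Positive: the spring extends the joint during stance, working with
    the ground-reaction moments; negative: it opposes them.
    """
    p = p or traj.params
    total, integral = 0.0, 0.0
    for index in (1, 2):
        for (t0, t1, _) in traj.stance_intervals(index):
            ts = np.linspace(t0, t1, 101)
            phis = traj.states_matrix(ts)[:, 3]
            integral += simpson(-4.0 * p.kt * phis, x=ts)
            total += t1 - t0
    if total == 0.0:
        raise IndeterminateBranchError("cycle has no stance phase")
    return float(integral / total)


def classify_branch(traj: Trajectory, p: ModelParameters | None = None,
                    tol: float = 1e-9) -> int:
    """Branch label of a symmetric periodic cycle.

    Branch 1 is the family with the spine *extended* at the apex
    (``phi > 0`` at the cycle-start section), Branch 2 the family with
    it flexed — the upper and lower solution families in the
    (apex height, apex spine angle) plane.  Away from Branch 1's
    small-height tail this coincides with the sign of the stance-phase
    spring-torque alignment (:func:`stance_spring_alignment`): Branch 1
    solutions keep ``phi < 0`` through stance so the spring works with
    the ground-reaction moments, Branch 2 solutions the reverse.
    """
    phi0 = float(traj.initial_state().cont.q[3])
    if abs(phi0) < tol:
        raise IndeterminateBranchError(
            f"apex spine angle {phi0:.2e} rad is indeterminate")
    return 1 if phi0 > 0 else 2


# --------------------------------------------------------------------- #
# fluctuations and velocity

def fluctuations(traj: Trajectory, n: int = 2001) -> GaitCharacteristics:
    """Max-minus-min of y, theta and phi over the cycle (dense output)."""
    df = traj.sample(n)
    return GaitCharacteristics(
        float(df["y"].max() - df["y"].min()),
        float(df["theta"].max() - df["theta"].min()),
        float(df["phi"].max() - df["phi"].min()))


def average_velocity(traj: Trajectory) -> float:
    """Average horizontal velocity over the cycle, ``dx / T``."""
    x0 = traj.initial_state().cont.q[0]
    x1 = traj.final_state().cont.q[0]
    return float((x1 - x0) / traj.duration)


# --------------------------------------------------------------------- #
# impulses

def _stance_samples(traj: Trajectory, t0: float, t1: float, leg: LegState,
                    n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Spring force magnitude and leg angle on a dense stance grid."""
    p = traj.params
    ts = np.linspace(t0, t1, n)
    states = traj.states_matrix(ts)
    x, y, th, ph = states[:, 0], states[:, 1], states[:, 2], states[:, 3]
    s, a = leg.sign, p.hip_offset
    hx = x + s * a * np.cos(th) * np.cos(ph) - p.d * np.sin(th) * np.sin(ph)
    hy = y + s * a * np.sin(th) * np.cos(ph) + p.d * np.cos(th) * np.sin(ph)
    l = np.hypot(hx - leg.toe_x, hy)
    force = p.k * (p.l0 - l)
    gamma = np.arctan2(leg.toe_x - hx, hy)
    return ts, force, gamma


def _leg_impulses(traj: Trajectory, index: int, n: int
                  ) -> tuple[float, float, float, float]:
    """(p_net, p_x_neg, p_x_pos, p_y) of one leg over its stance."""
    p = traj.params
    p_net = p_neg = p_pos = p_y = 0.0
    for (t0, t1, leg) in traj.stance_intervals(index):
        ts, force, gamma = _stance_samples(traj, t0, t1, leg, n)
        p_net += -simpson(force, x=ts)
        p_y += simpson(force * np.cos(gamma), x=ts)
        fx = -force * np.sin(gamma)
        if gamma[0] > 0 > gamma[-1]:
            g_of_t = lambda t: leg_angle(traj.state_at(t).cont.q, leg, p)
            t_split = brentq(g_of_t, t0, t1, xtol=1e-12)
            n_half = n // 2 * 2 + 1
            for (a, b, sign) in ((t0, t_split, "neg"), (t_split, t1, "pos")):
                tss, f, g = _stance_samples(traj, a, b, leg, n_half)
                val = simpson(-f * np.sin(g), x=tss)
                if sign == "neg":
                    p_neg += val
                else:
                    p_pos += val
        else:
            warnings.warn(
                f"leg {index}: leg angle does not cross zero in stance; "
                "assigning the whole stance to one sign", stacklevel=2)
            val = simpson(fx, x=ts)
            if gamma[0] > 0:
                p_neg += val
            else:
                p_pos += val
    return p_net, p_neg, p_pos, p_y


def impulses(traj: Trajectory, p: ModelParameters | None = None,
             n: int = 401) -> PerformanceMetrics:
    """Per-leg ground-reaction impulses of one cycle.

    The braking/propulsive split is at the instant the leg passes the
    vertical (leg angle zero); integrals use composite Simpson on dense
    output.  For symmetric periodic cycles ``p2x_pos = -p1x_neg`` and
    ``p2x_neg = -p1x_pos`` hold, and ``p_y`` per leg balances half the
    weight impulse ``m g T``.
    """
    p = p or traj.params
    p1, p1n, p1p, p1y = _leg_impulses(traj, 1, n)
    p2, p2n, p2p, p2y = _leg_impulses(traj, 2, n)
    if p1y > 0 and p2y > 0:
        rel = abs(p1y - p2y) / max(p1y, p2y)
        if rel > 1e-4:
            logger.debug("per-leg vertical impulses differ by %.2e", rel)
    return PerformanceMetrics(
        v_bar=average_velocity(traj),
        p_net=0.5 * (p1 + p2),
        p1x_neg=p1n, p1x_pos=p1p, p2x_neg=p2n, p2x_pos=p2p,
        p_y=0.5 * (p1y + p2y))


def impulses_augmented(traj: Trajectory, p: ModelParameters | None = None,
                       rtol: float = 1e-12, atol: float = 1e-12
                       ) -> PerformanceMetrics:
    """Impulses by augmented-state integration (independent oracle).

    Re-integrates each stance window appending the running impulse
    integrals to the ODE state instead of quadrature on dense output.
    """
    from .model import _make_rhs  # shared smooth RHS
    p = p or traj.params

    def windows(index: int, t0: float, t1: float, leg: LegState
                ) -> list[tuple[float, float, tuple]]:
        """Sub-windows of [t0, t1] that are smooth (fixed leg modes) and
        have a constant sign of the leg angle."""
        cuts = {t0, t1}
        for seg in traj.segments:
            if t0 < seg.t0 < t1:
                cuts.add(seg.t0)
        g_of_t = lambda t: leg_angle(traj.state_at(t).cont.q, leg, p)
        ts = np.linspace(t0, t1, 201)
        gs = np.array([g_of_t(t) for t in ts])
        for i in range(len(ts) - 1):
            if gs[i] * gs[i + 1] < 0:
                cuts.add(brentq(g_of_t, ts[i], ts[i + 1], xtol=1e-13))
        edges = sorted(cuts)
        return [(a, b, traj._segment_at(0.5 * (a + b)).legs)
                for a, b in zip(edges[:-1], edges[1:])]

    def leg_vals(index: int) -> tuple[float, float, float, float]:
        p_net = p_neg = p_pos = p_y = 0.0
        for (t0, t1, leg) in traj.stance_intervals(index):
            for (a, b, legs) in windows(index, t0, t1, leg):
                base = _make_rhs(legs, p)

                def rhs(t, s):
                    ds = np.empty(11)
                    ds[:8] = base(t, s[:8])
                    q = s[:4]
                    l = leg_length(q, leg, p)
                    g = leg_angle(q, leg, p)
                    f = p.k * (p.l0 - l)
                    ds[8] = -f
                    ds[9] = -f * math.sin(g)
                    ds[10] = f * math.cos(g)
                    return ds

                s0 = np.concatenate([traj.state_at(a).cont.vector,
                                     np.zeros(3)])
                sol = solve_ivp(rhs, (a, b), s0, method="DOP853",
                                rtol=rtol, atol=atol)
                if not sol.success:
                    raise RuntimeError(sol.message)
                p_net += sol.y[8, -1]
                p_y += sol.y[10, -1]
                g_mid = leg_angle(traj.state_at(0.5 * (a + b)).cont.q, leg, p)
                if g_mid > 0:
                    p_neg += sol.y[9, -1]
                else:
                    p_pos += sol.y[9, -1]
        return p_net, p_neg, p_pos, p_y

    p1, p1n, p1p, p1y = leg_vals(1)
    p2, p2n, p2p, p2y = leg_vals(2)
    return PerformanceMetrics(
        v_bar=average_velocity(traj),
        p_net=0.5 * (p1 + p2),
        p1x_neg=p1n, p1x_pos=p1p, p2x_neg=p2n, p2x_pos=p2p,
        p_y=0.5 * (p1y + p2y))


# --------------------------------------------------------------------- #
# spine torque decomposition

def torque_decomposition(traj: Trajectory, p: ModelParameters | None = None,
                         n: int = 1001) -> TorqueDecomposition:
    """Spine-spring torque and leg GRF moments on phi, extension-positive.

    ``tau_t = -4 kt phi``; ``tau_i = -k (l_i - l0) dl_i/dphi`` for a
    stance leg (zero in the air): the negatives of the corresponding
    rows of the potential gradient, so positive values extend the spine.
    """
    p = p or traj.params
    ts = traj.sample_times(n)
    states = traj.states_matrix(ts)
    tau_t = -4.0 * p.kt * states[:, 3]
    tau = {1: np.zeros(n), 2: np.zeros(n)}
    for index in (1, 2):
        for (t0, t1, leg) in traj.stance_intervals(index):
            mask = (ts >= t0) & (ts <= t1)
            x, y = states[mask, 0], states[mask, 1]
            th, ph = states[mask, 2], states[mask, 3]
            s, a = leg.sign, p.hip_offset
            cth, sth = np.cos(th), np.sin(th)
            cph, sph = np.cos(ph), np.sin(ph)
            hx = x + s * a * cth * cph - p.d * sth * sph
            hy = y + s * a * sth * cph + p.d * cth * sph
            dx, dy = hx - leg.toe_x, hy
            l = np.hypot(dx, dy)
            dldphi = (dx * (-s * a * cth * sph - p.d * sth * cph)
                      + dy * (-s * a * sth * sph + p.d * cth * cph)) / l
            tau[index][mask] = -p.k * (l - p.l0) * dldphi
    return TorqueDecomposition(ts, tau_t, tau[1], tau[2])


# --------------------------------------------------------------------- #
# comparison with measured statistics

def compare_to_reference(chars: GaitCharacteristics,
                         ref: dict[str, tuple[float, float]]
                         ) -> dict[str, dict[str, float | bool]]:
    """Standardized deviations from reference (mean, SE) statistics.

    Returns per characteristic the z-like score ``(value - mean) / SE``
    and whether the value lies inside the one-SE band.
    """
    out: dict[str, dict[str, float | bool]] = {}
    for name in ("delta_y", "delta_theta", "delta_phi"):
        mean, se = ref[name]
        if se == 0:
            raise ZeroDivisionError(f"zero SE for {name}")
        value = getattr(chars, name)
        score = (value - mean) / se
        out[name] = {"value": value, "mean": mean, "se": se,
                     "score": score, "within_se": bool(abs(score) <= 1.0)}
    return out
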
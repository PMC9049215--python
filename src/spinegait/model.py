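"""Hybrid dynamics of the planar two-body bounding model.

State and geometry
------------------
Generalized coordinates are ``q = [x, y, theta, phi]``: horizontal and
vertical position of the whole-body COM, pitch angle of the line joining
the two body COMs, and the spine half angle (the anatomical spine-joint
angle is ``2 phi``, positive in extension).  The full continuous state is
the 8-vector ``[q, qdot]``.

The equations of motion are ``M(q) qddot + h(q, qdot) + v(q) = 0`` with a
diagonal mass matrix.  Body ``i`` has orientation ``psi_i = theta +
s_i phi`` (``s_i = (-1)^i``), and its leg joint sits a distance ``d``
beyond the body COM along the body axis (away from the spine joint),
which puts the hip of leg ``i`` at

    hip_i = (x + s_i (r+d) cos(theta) cos(phi) - d sin(theta) sin(phi),
             y + s_i (r+d) sin(theta) cos(phi) + d cos(theta) sin(phi)),

so Leg 2's hip leads when travelling in +x, and spine extension
(``phi > 0``) raises both hips while flexion lowers them — the
``d``-dependent asymmetry between extended and gathered postures.  In
the air a leg keeps its
nominal length ``l0`` and its touchdown angle ``gamma_td`` (measured from
the vertical, positive when the toe is ahead of the hip).  At touchdown
the toe becomes a frictionless pin on the ground; the leg spring loads in
compression only and the leg lifts off when it returns to ``l0``, at
which instant its angle snaps back to ``gamma_td``.  Touchdown and
liftoff both occur at the rest length, so the model conserves energy.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .params import ModelParameters, SolverSettings

__all__ = [
    "LegMode", "LegState", "ContinuousState", "HybridState", "Event",
    "Trajectory", "SimulationError", "NoContactError", "CrashError",
    "SequenceError", "DegenerateContactError", "StanceApexError",
    "mass_matrix", "hip_position", "leg_length", "leg_length_gradient",
    "leg_angle", "generalized_forces", "dynamics_rhs", "total_energy",
    "touchdown_value", "liftoff_value", "simulate",
]

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------- #
# failure taxonomy

class SimulationError(RuntimeError):
    """Base class for hybrid-simulation failures."""


class NoContactError(SimulationError):
    """No touchdown (or no closing apex) occurred within the horizon."""


class CrashError(SimulationError):
    """A hip or the COM reached the ground."""


class SequenceError(SimulationError):
    """A leg attempted a second stance before the cycle closed."""


class DegenerateContactError(SimulationError):
    """Grazing contact: stance shorter than the degeneracy tolerance."""


class StanceApexError(SimulationError):
    """The closing apex occurred while a leg was still on the ground."""


# --------------------------------------------------------------------- #
# types

class LegMode(str, Enum):
    AIR = "air"
    STANCE = "stance"


@dataclass(frozen=True)
class LegState:
    """Discrete state of one massless spring leg.

    ``toe_x`` is the ground anchor abscissa and is defined iff the leg is
    in stance; in the air the leg has length ``l0`` and holds
    ``gamma_td``.
    """

    index: int                      # 1 or 2
    mode: LegMode = LegMode.AIR
    gamma_td: float = 0.0
    toe_x: float | None = None

    def __post_init__(self) -> None:
        if self.index not in (1, 2):
            raise ValueError("leg index must be 1 or 2")
        if (self.mode is LegMode.STANCE) != (self.toe_x is not None):
            raise ValueError("toe_x must be set exactly when the leg is in stance")

    @property
    def sign(self) -> float:
        """Hip placement sign ``(-1)**index``."""
        return -1.0 if self.index == 1 else 1.0


@dataclass(frozen=True)
class ContinuousState:
    """Continuous part of the hybrid state: ``q``, ``qdot`` and time."""

    q: np.ndarray
    qdot: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "q", np.asarray(self.q, dtype=float))
        object.__setattr__(self, "qdot", np.asarray(self.qdot, dtype=float))
        if self.q.shape != (4,) or self.qdot.shape != (4,):
            raise ValueError("q and qdot must be 4-vectors")
        if not (np.all(np.isfinite(self.q)) and np.all(np.isfinite(self.qdot))):
            raise ValueError("non-finite state")

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([self.q, self.qdot])


@dataclass(frozen=True)
class HybridState:
    cont: ContinuousState
    legs: tuple[LegState, LegState]

    def __post_init__(self) -> None:
        if tuple(l.index for l in self.legs) != (1, 2):
            raise ValueError("legs must be (leg 1, leg 2)")

    @property
    def phase(self) -> str:
        n = sum(1 for l in self.legs if l.mode is LegMode.STANCE)
        return ("flight", "single_stance", "double_stance")[n]


@dataclass(frozen=True)
class Event:
    t: float
    kind: str                       # touchdown1|touchdown2|liftoff1|liftoff2|apex
    state: HybridState


@dataclass
class _Segment:
    """One smooth phase: dense ODE solution plus frozen leg modes."""

    t0: float
    t1: float
    legs: tuple[LegState, LegState]
    sol: object                     # scipy OdeSolution (dense output)

    def state_vector(self, t: float) -> np.ndarray:
        return np.asarray(self.sol(t), dtype=float)


class Trajectory:
    """Event-driven trajectory: ordered smooth segments with dense
    output, plus the event log.  Exposes interpolation at arbitrary
    times, uniform sampling to a tidy frame, and energy diagnostics."""

    def __init__(self, segments: Sequence[_Segment], events: Sequence[Event],
                 params: ModelParameters):
        if not segments:
            raise ValueError("empty trajectory")
        self.segments = list(segments)
        self.events = sorted(events, key=lambda e: e.t)
        self.params = params
        times = [s.t0 for s in self.segments] + [self.segments[-1].t1]
        if not np.all(np.diff(times) > 0):
            raise ValueError("segment times must be strictly increasing")

    # -- basic accessors ------------------------------------------------
    @property
    def t0(self) -> float:
        return self.segments[0].t0

    @property
    def t1(self) -> float:
        return self.segments[-1].t1

    @property
    def duration(self) -> float:
        return self.t1 - self.t0

    def _segment_at(self, t: float) -> _Segment:
        if not (self.t0 - 1e-12 <= t <= self.t1 + 1e-12):
            raise ValueError(f"time {t} outside trajectory [{self.t0}, {self.t1}]")
        for seg in self.segments:
            if t <= seg.t1 + 1e-12:
                return seg
        return self.segments[-1]

    def state_at(self, t: float) -> HybridState:
        seg = self._segment_at(t)
        tt = min(max(t, seg.t0), seg.t1)
        s = seg.state_vector(tt)
        return HybridState(ContinuousState(s[:4], s[4:], t=tt), seg.legs)

    def initial_state(self) -> HybridState:
        return self.state_at(self.t0)

    def final_state(self) -> HybridState:
        return self.state_at(self.t1)

    # -- sampling -------------------------------------------------------
    def sample_times(self, n: int = 1001) -> np.ndarray:
        return np.linspace(self.t0, self.t1, n)

    def states_matrix(self, ts: np.ndarray) -> np.ndarray:
        """Vectorized dense-output evaluation: (len(ts), 8) state rows.

        ``ts`` must be sorted and lie within the trajectory span; each
        segment's interpolant is evaluated on its block of times."""
        ts = np.asarray(ts, dtype=float)
        out = np.empty((len(ts), 8))
        edges = np.array([seg.t1 for seg in self.segments])
        idx = np.searchsorted(edges, ts, side="left")
        idx = np.clip(idx, 0, len(self.segments) - 1)
        for k in np.unique(idx):
            seg = self.segments[k]
            mask = idx == k
            tt = np.clip(ts[mask], seg.t0, seg.t1)
            out[mask] = np.asarray(seg.sol(tt)).T
        return out

    def sample(self, n: int = 1001) -> pd.DataFrame:
        """Uniform dense sampling as a tidy frame, one row per instant."""
        ts = self.sample_times(n)
        rows = self.states_matrix(ts)
        edges = np.array([seg.t1 for seg in self.segments])
        idx = np.clip(np.searchsorted(edges, ts, side="left"), 0,
                      len(self.segments) - 1)
        df = pd.DataFrame(rows, columns=["x", "y", "theta", "phi",
                                         "xdot", "ydot", "thetadot", "phidot"])
        df.insert(0, "t", ts)
        df["mode_leg1"] = [self.segments[k].legs[0].mode.value for k in idx]
        df["mode_leg2"] = [self.segments[k].legs[1].mode.value for k in idx]
        return df

    def phases(self) -> list[tuple[float, float, str, tuple[LegState, LegState]]]:
        """Merged list of (t0, t1, phase label, legs) intervals."""
        out: list[tuple[float, float, str, tuple[LegState, LegState]]] = []
        for seg in self.segments:
            label = ("flight", "single_stance", "double_stance")[
                sum(1 for l in seg.legs if l.mode is LegMode.STANCE)]
            if out and out[-1][2] == label and out[-1][3] == seg.legs:
                out[-1] = (out[-1][0], seg.t1, label, seg.legs)
            else:
                out.append((seg.t0, seg.t1, label, seg.legs))
        return out

    def stance_intervals(self, index: int) -> list[tuple[float, float, LegState]]:
        """Stance windows of leg ``index`` as (t0, t1, leg state)."""
        out = []
        for seg in self.segments:
            leg = seg.legs[index - 1]
            if leg.mode is LegMode.STANCE:
                if out and abs(out[-1][1] - seg.t0) < 1e-12 and out[-1][2] == leg:
                    out[-1] = (out[-1][0], seg.t1, leg)
                else:
                    out.append((seg.t0, seg.t1, leg))
        return out

    # -- diagnostics ----------------------------------------------------
    def energy(self, t: float) -> float:
        return total_energy(self.state_at(t), self.params)

    def energy_drift(self, n: int = 201) -> float:
        """Max relative deviation of total energy from its initial value."""
        e0 = self.energy(self.t0)
        ts = self.sample_times(n)
        emax = max(abs(self.energy(t) - e0) for t in ts)
        return emax / abs(e0)

    def to_csv(self, path, n: int = 1001) -> None:
        self.sample(n).to_csv(path, index=False)

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame([(e.t, e.kind) for e in self.events],
                            columns=["t", "kind"])


# --------------------------------------------------------------------- #
# kinematics and dynamics

def mass_matrix(q: np.ndarray, p: ModelParameters) -> np.ndarray:
    """Diagonal mass matrix ``diag(2m, 2m, 2J + 2 m r^2 cos^2 phi,
    2J + 2 m r^2 sin^2 phi)``."""
    phi = q[3]
    mr2 = p.m * p.r ** 2
    return np.diag([2.0 * p.m, 2.0 * p.m,
                    2.0 * p.J + 2.0 * mr2 * math.cos(phi) ** 2,
                    2.0 * p.J + 2.0 * mr2 * math.sin(phi) ** 2])


def hip_position(q: np.ndarray, index: int, p: ModelParameters) -> tuple[float, float]:
    """Hip (leg joint) point of leg ``index`` for coordinates ``q``:
    distance ``d`` beyond the body COM along the body axis."""
    s = -1.0 if index == 1 else 1.0
    a = p.hip_offset
    x, y, th, ph = q[0], q[1], q[2], q[3]
    cth, sth = math.cos(th), math.sin(th)
    cph, sph = math.cos(ph), math.sin(ph)
    return (x + s * a * cth * cph - p.d * sth * sph,
            y + s * a * sth * cph + p.d * cth * sph)


def leg_length(q: np.ndarray, leg: LegState, p: ModelParameters) -> float:
    """Current leg length; ``l0`` by definition in the air."""
    if leg.mode is LegMode.AIR:
        return p.l0
    hx, hy = hip_position(q, leg.index, p)
    return math.hypot(hx - leg.toe_x, hy)


def leg_length_gradient(q: np.ndarray, leg: LegState, p: ModelParameters) -> np.ndarray:
    """Analytic ``d l_i / d q`` for a stance leg."""
    if leg.mode is not LegMode.STANCE:
        raise ValueError("leg length gradient defined only in stance")
    s = leg.sign
    a, d = p.hip_offset, p.d
    th, ph = q[2], q[3]
    cth, sth = math.cos(th), math.sin(th)
    cph, sph = math.cos(ph), math.sin(ph)
    hx = q[0] + s * a * cth * cph - d * sth * sph
    hy = q[1] + s * a * sth * cph + d * cth * sph
    dx = hx - leg.toe_x
    dy = hy
    l = math.hypot(dx, dy)
    dth = (dx * (-s * a * sth * cph - d * cth * sph)
           + dy * (s * a * cth * cph - d * sth * sph)) / l
    dph = (dx * (-s * a * cth * sph - d * sth * cph)
           + dy * (-s * a * sth * sph + d * cth * cph)) / l
    return np.array([dx / l, dy / l, dth, dph])


def leg_angle(q: np.ndarray, leg: LegState, p: ModelParameters) -> float:
    """Leg angle from the vertical, positive when the toe is ahead of
    the hip in +x.  Equals ``gamma_td`` in the air."""
    if leg.mode is LegMode.AIR:
        return leg.gamma_td
    hx, hy = hip_position(q, leg.index, p)
    return math.atan2(leg.toe_x - hx, hy)


def generalized_forces(q: np.ndarray, qdot: np.ndarray,
                       legs: Iterable[LegState], p: ModelParameters
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Velocity-dependent vector ``h(q, qdot)`` and potential-gradient
    vector ``v(q)`` of the equations of motion."""
    ph = q[3]
    thd, phd = qdot[2], qdot[3]
    cph, sph = math.cos(ph), math.sin(ph)
    mr2 = p.m * p.r ** 2
    h = np.array([0.0, 0.0,
                  -4.0 * mr2 * thd * phd * cph * sph,
                  2.0 * mr2 * (thd ** 2 + phd ** 2) * cph * sph])
    v = np.array([0.0, 2.0 * p.m * p.g, 0.0, 4.0 * p.kt * ph])
    for leg in legs:
        if leg.mode is LegMode.STANCE:
            l = leg_length(q, leg, p)
            v = v + p.k * (l - p.l0) * leg_length_gradient(q, leg, p)
    return h, v


def dynamics_rhs(state: HybridState, p: ModelParameters) -> np.ndarray:
    """Generalized accelerations solving ``M qddot = -h - v``."""
    q, qdot = state.cont.q, state.cont.qdot
    h, v = generalized_forces(q, qdot, state.legs, p)
    minv = 1.0 / np.diag(mass_matrix(q, p))
    return -(h + v) * minv


def total_energy(state: HybridState, p: ModelParameters) -> float:
    """Total mechanical energy: kinetic + gravity + spine spring + any
    loaded leg springs (compression only)."""
    q, qdot = state.cont.q, state.cont.qdot
    M = mass_matrix(q, p)
    e = 0.5 * qdot @ M @ qdot + 2.0 * p.m * p.g * q[1] + 2.0 * p.kt * q[3] ** 2
    for leg in state.legs:
        if leg.mode is LegMode.STANCE:
            e += 0.5 * p.k * (p.l0 - leg_length(q, leg, p)) ** 2
    return e


# --------------------------------------------------------------------- #
# guard functions

def touchdown_value(state: HybridState, leg: LegState, p: ModelParameters) -> float:
    """Toe height of an air leg; zero at ground contact."""
    if leg.mode is not LegMode.AIR:
        raise ValueError("touchdown guard applies to air legs")
    _, hy = hip_position(state.cont.q, leg.index, p)
    return hy - p.l0 * math.cos(leg.gamma_td)


def liftoff_value(state: HybridState, leg: LegState, p: ModelParameters) -> float:
    """Compression ``l0 - l_i`` of a stance leg; zero at liftoff."""
    if leg.mode is not LegMode.STANCE:
        raise ValueError("liftoff guard applies to stance legs")
    return p.l0 - leg_length(state.cont.q, leg, p)


# --------------------------------------------------------------------- #
# event-driven integration

def _make_rhs(legs: tuple[LegState, LegState], p: ModelParameters) -> Callable:
    """Smooth RHS for fixed leg modes, written out for speed."""
    m2 = 2.0 * p.m
    mr2 = p.m * p.r ** 2
    J2 = 2.0 * p.J
    mg2 = 2.0 * p.m * p.g
    kt4 = 4.0 * p.kt
    a, d = p.hip_offset, p.d
    k, l0 = p.k, p.l0
    stance = [(l.sign, l.toe_x) for l in legs if l.mode is LegMode.STANCE]

    def rhs(t: float, s: np.ndarray) -> np.ndarray:
        x, y, th, ph, xd, yd, thd, phd = s
        cph, sph = math.cos(ph), math.sin(ph)
        cth, sth = math.cos(th), math.sin(th)
        v0 = 0.0
        v1 = mg2
        v2 = 0.0
        v3 = kt4 * ph
        for sg, toe in stance:
            hx = x + sg * a * cth * cph - d * sth * sph
            hy = y + sg * a * sth * cph + d * cth * sph
            dx = hx - toe
            dy = hy
            l = math.sqrt(dx * dx + dy * dy)
            f = k * (l - l0) / l
            v0 += f * dx
            v1 += f * dy
            v2 += f * (dx * (-sg * a * sth * cph - d * cth * sph)
                       + dy * (sg * a * cth * cph - d * sth * sph))
            v3 += f * (dx * (-sg * a * cth * sph - d * sth * cph)
                       + dy * (-sg * a * sth * sph + d * cth * cph))
        cs = cph * sph
        h2 = -4.0 * mr2 * thd * phd * cs
        h3 = 2.0 * mr2 * (thd * thd + phd * phd) * cs
        m33 = J2 + 2.0 * mr2 * cph * cph
        m44 = J2 + 2.0 * mr2 * sph * sph
        return np.array([xd, yd, thd, phd,
                         -v0 / m2, -v1 / m2, -(h2 + v2) / m33, -(h3 + v3) / m44])

    return rhs


def _apply_touchdown(s: np.ndarray, leg: LegState, p: ModelParameters) -> LegState:
    hx, _ = hip_position(s[:4], leg.index, p)
    return replace(leg, mode=LegMode.STANCE,
                   toe_x=hx + p.l0 * math.sin(leg.gamma_td))


def _apply_liftoff(leg: LegState) -> LegState:
    return replace(leg, mode=LegMode.AIR, toe_x=None)


def simulate(start: HybridState, p: ModelParameters,
             stop: str | tuple[str, float] = "cycle",
             settings: SolverSettings | None = None) -> Trajectory:
    """Integrate the hybrid dynamics with event handling.

    Parameters
    ----------
    start : HybridState
        Initial state; stance legs must be at or below nominal length
        with the toe on the ground.
    stop : "cycle" or ("time", T)
        ``"cycle"`` runs until the first apex (descending zero of
        ``ydot`` in flight) after both legs completed exactly one
        stance; ``("time", T)`` integrates a fixed horizon with no
        sequencing constraints.
    settings : SolverSettings, optional
        Integrator tolerances, horizon and degeneracy tolerances.

    Raises
    ------
    NoContactError, CrashError, SequenceError, DegenerateContactError,
    StanceApexError
        The failure taxonomy of cycle construction; ``("time", T)`` runs
        only raise :class:`CrashError`.
    """
    cfg = settings or SolverSettings()
    cyclic = stop == "cycle"
    if cyclic:
        horizon = cfg.horizon
    else:
        kind, horizon = stop
        if kind != "time":
            raise ValueError(f"unknown stop condition {stop!r}")

    t = float(start.cont.t)
    t_end = t + horizon
    s = start.cont.vector.copy()
    legs = tuple(start.legs)
    touch_count = {1: 0, 2: 0}
    stance_started = {l.index: t for l in legs if l.mode is LegMode.STANCE}
    for l in legs:
        if l.mode is LegMode.STANCE:
            touch_count[l.index] = 1

    segments: list[_Segment] = []
    events: list[Event] = []

    while t < t_end - 1e-13:
        rhs = _make_rhs(legs, p)
        ev_funcs: list[Callable] = []
        ev_tags: list[tuple[str, int]] = []

        for leg in legs:
            if leg.mode is LegMode.AIR:
                gcos = p.l0 * math.cos(leg.gamma_td)
                sgn, a = leg.sign, p.hip_offset

                def g_td(tt, ss, sgn=sgn, a=a, gcos=gcos):
                    return (ss[1] + sgn * a * math.sin(ss[2]) * math.cos(ss[3])
                            + p.d * math.cos(ss[2]) * math.sin(ss[3]) - gcos)
                g_td.terminal = True
                g_td.direction = -1
                ev_funcs.append(g_td)
                ev_tags.append(("touchdown", leg.index))
            else:
                sgn, a, toe = leg.sign, p.hip_offset, leg.toe_x

                def g_lo(tt, ss, sgn=sgn, a=a, toe=toe):
                    cth, sth = math.cos(ss[2]), math.sin(ss[2])
                    cph, sph = math.cos(ss[3]), math.sin(ss[3])
                    hx = ss[0] + sgn * a * cth * cph - p.d * sth * sph
                    hy = ss[1] + sgn * a * sth * cph + p.d * cth * sph
                    return p.l0 - math.hypot(hx - toe, hy)
                g_lo.terminal = True
                g_lo.direction = -1
                ev_funcs.append(g_lo)
                ev_tags.append(("liftoff", leg.index))

        for sgn_c in (-1.0, 1.0):
            def g_crash(tt, ss, sgn=sgn_c, a=p.hip_offset):
                return (ss[1] + sgn * a * math.sin(ss[2]) * math.cos(ss[3])
                        + p.d * math.cos(ss[2]) * math.sin(ss[3]))
            g_crash.terminal = True
            g_crash.direction = -1
            ev_funcs.append(g_crash)
            ev_tags.append(("crash", 0))

        both_done = touch_count[1] >= 1 and touch_count[2] >= 1
        if cyclic and both_done:
            # arm the apex guard once both stances are complete; firing
            # during stance is the stance-apex failure mode
            def g_apex(tt, ss):
                return ss[5]
            g_apex.terminal = True
            g_apex.direction = -1
            ev_funcs.append(g_apex)
            ev_tags.append(("apex", 0))

        sol = solve_ivp(rhs, (t, t_end), s, method="DOP853",
                        rtol=cfg.rtol, atol=cfg.atol,
                        events=ev_funcs, dense_output=True)
        if not sol.success:
            raise SimulationError(f"integrator failure: {sol.message}")

        # earliest event, touchdown before liftoff on ties
        fired: list[tuple[float, int]] = []
        for i, te in enumerate(sol.t_events):
            if len(te):
                fired.append((float(te[0]), i))
        if not fired:
            segments.append(_Segment(t, t_end, legs, sol.sol))
            t = t_end
            s = np.asarray(sol.sol(t_end), dtype=float)
            break

        t_min = min(f[0] for f in fired)
        near = [i for (te, i) in fired if te <= t_min + 1e-12]
        near.sort(key=lambda i: 0 if ev_tags[i][0] == "touchdown" else 1)
        idx = near[0]
        kind, leg_idx = ev_tags[idx]
        t_ev = float(sol.t_events[idx][0])
        s_ev = np.asarray(sol.y_events[idx][0], dtype=float)

        if t_ev > t + 1e-13:
            segments.append(_Segment(t, t_ev, legs, sol.sol))

        hs_before = HybridState(ContinuousState(s_ev[:4], s_ev[4:], t=t_ev), legs)

        if kind == "crash":
            raise CrashError(f"hip reached the ground at t={t_ev:.6f}")
        if kind == "apex":
            for l in legs:
                if l.mode is LegMode.STANCE:
                    raise StanceApexError(f"apex during stance at t={t_ev:.6f}")
            events.append(Event(t_ev, "apex", hs_before))
            t, s = t_ev, s_ev
            break
        if kind == "touchdown":
            if cyclic and touch_count[leg_idx] >= 1:
                raise SequenceError(
                    f"leg {leg_idx} touched down twice before cycle closure")
            touch_count[leg_idx] += 1
            stance_started[leg_idx] = t_ev
            new_leg = _apply_touchdown(s_ev, legs[leg_idx - 1], p)
        else:  # liftoff
            dur = t_ev - stance_started.get(leg_idx, t)
            if dur < cfg.grazing_tol:
                raise DegenerateContactError(
                    f"leg {leg_idx} stance lasted {dur:.3e} s")
            new_leg = _apply_liftoff(legs[leg_idx - 1])

        legs = tuple(new_leg if l.index == leg_idx else l for l in legs)
        events.append(Event(t_ev, f"{kind}{leg_idx}",
                            HybridState(ContinuousState(s_ev[:4], s_ev[4:], t=t_ev),
                                        legs)))
        t, s = t_ev, s_ev

    if cyclic:
        closed = any(e.kind == "apex" for e in events)
        if not closed:
            if touch_count[1] == 0 and touch_count[2] == 0:
                raise NoContactError("no touchdown within the horizon")
            raise NoContactError("cycle did not close within the horizon")

    traj = Trajectory(segments, events, p)
    drift = traj.energy_drift(51)
    if drift > cfg.energy_tol:
        logger.warning("energy drift %.3e exceeds tolerance %.3e",
                       drift, cfg.energy_tol)
    return traj
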
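"""Periodic-gait search on the apex Poincaré section.

The section is taken at the apex of the COM (``ydot = 0``, descending),
with the symmetry constraints ``theta = 0`` and ``phidot = 0`` imposed at
the section so that the search targets left–right symmetric bounding
cycles.  Section coordinates are ``z = [y, phi, thetadot]``; the apex
horizontal speed is not a coordinate — it is recovered from the fixed
total energy ``E``.  Touchdown angles ``u = [gamma1_td, gamma2_td]`` are
the gait parameters.

A symmetric periodic solution is a zero of the three-component residual
(theta, phidot, y - y*) at the next apex, with the unknowns
``(phi*, gamma1_td, gamma2_td)`` at fixed ``(E, y*, thetadot*)``; full
periodicity of the remaining coordinates is verified afterwards.  Around
a fold (solution families that double back in ``y*``) the roles of
``phi*`` and ``y*`` are exchanged.  Branch families are traced by
natural-parameter continuation; orbital stability comes from a
finite-difference linearization of the full apex return map.
"""
from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .model import (HybridState, ContinuousState, LegState, LegMode,
                    Trajectory, SimulationError, simulate)
from .params import ModelParameters, SolverSettings

__all__ = [
    "SectionState", "SearchParameters", "PeriodicSolution", "BranchSweep",
    "EnergyInfeasibleError", "ConvergenceError", "AsymmetricFixedPointError",
    "xdot_from_energy", "apex_state", "poincare_map", "residual",
    "newton_solve", "find_solutions_at", "continuation_sweep",
    "floquet_eigenvalues",
]

logger = logging.getLogger(__name__)


class EnergyInfeasibleError(ValueError):
    """The requested section state exceeds the available total energy."""


class ConvergenceError(RuntimeError):
    """Newton iteration failed to reach the residual tolerance."""


class AsymmetricFixedPointError(ConvergenceError):
    """Residual converged but the full return map is not periodic."""


@dataclass(frozen=True)
class SectionState:
    """Apex-section coordinates ``z = [y, phi, thetadot]``.

    By construction of the section, ``theta = 0``, ``phidot = 0`` and
    ``ydot = 0`` at the apex; ``xdot`` is recovered from the energy."""

    y: float
    phi: float
    thetadot: float

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.y, self.phi, self.thetadot])


@dataclass(frozen=True)
class SearchParameters:
    """Gait parameters: touchdown angles (rad) and total energy (J)."""

    gamma1_td: float
    gamma2_td: float
    E: float


@dataclass
class PeriodicSolution:
    """A converged symmetric periodic gait."""

    section: SectionState
    params: SearchParameters
    period: float
    trajectory: Trajectory
    residual_norm: float
    xdot: float
    branch: int | None = None
    gait_type: str | None = None
    floquet: np.ndarray | None = None
    stable: bool | None = None
    energy_drift: float | None = None

    @property
    def max_nontrivial_eigenvalue(self) -> float | None:
        """Largest modulus among eigenvalues other than the unit one."""
        if self.floquet is None:
            return None
        mags = np.abs(self.floquet)
        unit = int(np.argmin(np.abs(self.floquet - 1.0)))
        rest = np.delete(mags, unit)
        return float(rest.max()) if len(rest) else None

    def key(self) -> tuple:
        return (round(self.section.y, 6), round(self.section.phi, 6),
                round(self.params.gamma1_td, 6), round(self.params.gamma2_td, 6))


@dataclass
class BranchSweep:
    """All solutions found over a (y*, thetadot*) grid at one energy."""

    energy: float
    thetadot_values: tuple[float, ...]
    y_range: tuple[float, float]
    solutions: list[PeriodicSolution] = field(default_factory=list)
    failures: list[tuple[float, float, str]] = field(default_factory=list)

    def add(self, sol: PeriodicSolution) -> bool:
        key = sol.key()
        if any(s.key() == key for s in self.solutions):
            return False
        self.solutions.append(sol)
        return True

    def sort(self) -> None:
        self.solutions.sort(key=lambda s: (s.section.thetadot, s.section.y,
                                           s.section.phi))

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for s in self.solutions:
            rows.append({
                "E": self.energy,
                "thetadot_star": s.section.thetadot,
                "y_star": s.section.y,
                "phi_star": s.section.phi,
                "gamma1_td": s.params.gamma1_td,
                "gamma2_td": s.params.gamma2_td,
                "xdot_apex": s.xdot,
                "period": s.period,
                "branch": s.branch,
                "gait_type": s.gait_type,
                "residual_norm": s.residual_norm,
                "energy_drift": s.energy_drift,
                "max_abs_nontrivial_eigenvalue": s.max_nontrivial_eigenvalue,
                "stable": s.stable,
            })
        return pd.DataFrame(rows)


# --------------------------------------------------------------------- #
# section closure and map

def xdot_from_energy(z: SectionState, E: float, p: ModelParameters) -> float:
    """Unique non-negative apex horizontal speed closing the energy.

    At the apex (flight, ``ydot = phidot = 0``) the energy partition is
    ``E = m xdot^2 + (J + m r^2 cos^2 phi) thetadot^2 + 2 m g y
    + 2 kt phi^2``.
    """
    rot = (p.J + p.m * p.r ** 2 * math.cos(z.phi) ** 2) * z.thetadot ** 2
    rad = E - 2.0 * p.m * p.g * z.y - 2.0 * p.kt * z.phi ** 2 - rot
    if rad < 0.0:
        raise EnergyInfeasibleError(
            f"section state needs {-rad:.3f} J more than E = {E} J")
    return math.sqrt(rad / p.m)


def apex_state(z: SectionState, u: SearchParameters,
               p: ModelParameters) -> HybridState:
    """Full flight state at the section (``x = 0`` by convention)."""
    xd = xdot_from_energy(z, u.E, p)
    cont = ContinuousState(np.array([0.0, z.y, 0.0, z.phi]),
                           np.array([xd, 0.0, z.thetadot, 0.0]), t=0.0)
    legs = (LegState(1, LegMode.AIR, u.gamma1_td),
            LegState(2, LegMode.AIR, u.gamma2_td))
    return HybridState(cont, legs)


@dataclass
class PoincareResult:
    z_next: SectionState
    apex_theta: float
    apex_phidot: float
    period: float
    trajectory: Trajectory


def poincare_map(z: SectionState, u: SearchParameters, p: ModelParameters,
                 settings: SolverSettings | None = None) -> PoincareResult:
    """One application of the apex return map.

    Simulates from the (energy-closed) apex state until the next apex
    after both legs completed one stance, and returns the next section
    coordinates together with the slack variables ``theta`` and
    ``phidot`` at that apex (both vanish on symmetric periodic orbits).
    """
    start = apex_state(z, u, p)
    traj = simulate(start, p, stop="cycle", settings=settings)
    end = traj.final_state().cont
    z_next = SectionState(float(end.q[1]), float(end.q[3]), float(end.qdot[2]))
    return PoincareResult(z_next, float(end.q[2]), float(end.qdot[3]),
                          traj.duration, traj)


def residual(unknowns: Sequence[float], targets: tuple[float, float, float],
             p: ModelParameters, settings: SolverSettings | None = None
             ) -> tuple[np.ndarray, PoincareResult]:
    """Symmetric-periodicity residual at fixed ``(y*, thetadot*, E)``.

    ``unknowns = (phi*, gamma1_td, gamma2_td)``; returns the 3-vector
    ``(theta_next, phidot_next, y_next - y*)`` and the map evaluation.
    """
    y_star, thd_star, E = targets
    phi, g1, g2 = unknowns
    z = SectionState(y_star, phi, thd_star)
    u = SearchParameters(g1, g2, E)
    res = poincare_map(z, u, p, settings)
    r = np.array([res.apex_theta, res.apex_phidot, res.z_next.y - y_star])
    return r, res


def _residual_fixed_phi(unknowns: Sequence[float],
                        targets: tuple[float, float, float],
                        p: ModelParameters,
                        settings: SolverSettings | None = None
                        ) -> tuple[np.ndarray, PoincareResult]:
    """Fold-side residual: ``phi*`` fixed, apex height free.

    ``unknowns = (y*, gamma1_td, gamma2_td)`` at fixed
    ``(phi*, thetadot*, E)``; residual ``(theta, phidot, y_next - y*)``.
    """
    phi_star, thd_star, E = targets
    y, g1, g2 = unknowns
    z = SectionState(y, phi_star, thd_star)
    u = SearchParameters(g1, g2, E)
    res = poincare_map(z, u, p, settings)
    r = np.array([res.apex_theta, res.apex_phidot, res.z_next.y - y])
    return r, res


# --------------------------------------------------------------------- #
# Newton--Raphson with damping

def _newton(fun: Callable, w0: np.ndarray, tol: float, max_iter: int,
            fd_step: float, abort: Callable[[np.ndarray], bool] | None = None
            ) -> tuple[np.ndarray, np.ndarray, PoincareResult]:
    """Damped Newton on a 3-residual with forward-difference Jacobian.

    ``abort`` lets the caller cut off iterations drifting into a region
    known not to contain acceptable roots (the rigid-spine manifold)."""
    w = np.asarray(w0, dtype=float).copy()
    try:
        r, aux = fun(w)
    except (SimulationError, EnergyInfeasibleError) as exc:
        raise ConvergenceError(f"initial guess infeasible: {exc}") from exc
    for _ in range(max_iter):
        if abort is not None and abort(w):
            raise ConvergenceError("iteration entered an excluded region")
        nr = np.linalg.norm(r)
        if nr < tol:
            return w, r, aux
        J = np.empty((3, 3))
        for j in range(3):
            h = fd_step * max(1.0, abs(w[j]))
            wp = w.copy()
            wp[j] += h
            try:
                rp, _ = fun(wp)
            except (SimulationError, EnergyInfeasibleError):
                wp[j] = w[j] - h
                try:
                    rp, _ = fun(wp)
                except (SimulationError, EnergyInfeasibleError) as exc:
                    raise ConvergenceError(
                        f"Jacobian evaluation failed: {exc}") from exc
                h = -h
            J[:, j] = (rp - r) / h
        try:
            step = np.linalg.solve(J, -r)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular Jacobian") from exc
        lam = 1.0
        for _ in range(10):
            try:
                r_new, aux_new = fun(w + lam * step)
            except (SimulationError, EnergyInfeasibleError):
                lam *= 0.5
                continue
            if np.linalg.norm(r_new) < nr:
                break
            lam *= 0.5
        else:
            raise ConvergenceError(
                f"damping failed at residual norm {nr:.3e}")
        w = w + lam * step
        r, aux = r_new, aux_new
    if np.linalg.norm(r) < tol:
        return w, r, aux
    raise ConvergenceError(
        f"no convergence in {max_iter} iterations (|r| = {np.linalg.norm(r):.3e})")


def _finalize(z: SectionState, u: SearchParameters, r: np.ndarray,
              aux: PoincareResult, p: ModelParameters,
              settings: SolverSettings, periodicity_tol: float = 1e-8
              ) -> PeriodicSolution:
    """Verify full periodicity of the converged fixed point and label it."""
    if abs(z.phi) < 1e-9:
        # phi = 0 with phidot = 0 lies on the rigid-spine invariant
        # manifold: the whole cycle has no spine motion and belongs to a
        # degenerate family outside the bending branches
        raise ConvergenceError("converged to a rigid-spine solution")
    dz = np.abs(aux.z_next.vector - z.vector)
    slack = max(abs(aux.apex_theta), abs(aux.apex_phidot))
    if dz.max() > periodicity_tol or slack > periodicity_tol:
        raise AsymmetricFixedPointError(
            f"converged point is not fully periodic (|dz| = {dz.max():.2e}, "
            f"slack = {slack:.2e})")
    sol = PeriodicSolution(
        section=z, params=u, period=aux.period, trajectory=aux.trajectory,
        residual_norm=float(np.linalg.norm(r)),
        xdot=xdot_from_energy(z, u.E, p),
        energy_drift=aux.trajectory.energy_drift(101))
    from . import metrics  # local import: metrics depends on model only
    sol.gait_type = metrics.classify_type(aux.trajectory)
    sol.branch = metrics.classify_branch(aux.trajectory, p)
    return sol


def newton_solve(guess: Sequence[float], targets: tuple[float, float, float],
                 p: ModelParameters, settings: SolverSettings | None = None,
                 mode: str = "y") -> PeriodicSolution:
    """Solve for a symmetric periodic gait from an initial guess.

    ``mode="y"``: unknowns ``(phi*, g1, g2)`` at fixed
    ``(y*, thetadot*, E)`` targets.  ``mode="phi"``: unknowns
    ``(y*, g1, g2)`` at fixed ``(phi*, thetadot*, E)`` — used to round
    folds where the family doubles back in ``y*``.
    """
    cfg = settings or SolverSettings()
    if mode == "y":
        fun = lambda w: residual(w, targets, p, cfg)
        # heading into the rigid-spine manifold: no bending solution there
        abort = lambda w: abs(w[0]) < 1e-3
    elif mode == "phi":
        fun = lambda w: _residual_fixed_phi(w, targets, p, cfg)
        abort = None
    else:
        raise ValueError(f"unknown mode {mode!r}")
    w, r, aux = _newton(fun, np.asarray(guess, float), cfg.newton_tol,
                        cfg.newton_max_iter, cfg.newton_fd_step, abort=abort)
    if mode == "y":
        z = SectionState(targets[0], w[0], targets[1])
        u = SearchParameters(w[1], w[2], targets[2])
    else:
        z = SectionState(w[0], targets[0], targets[1])
        u = SearchParameters(w[1], w[2], targets[2])
    return _finalize(z, u, r, aux, p, cfg)


# --------------------------------------------------------------------- #
# seeding and continuation

def grid_scan(targets: tuple[float, float, float], p: ModelParameters,
              settings: SolverSettings | None = None,
              phi_range: tuple[float, float] = (-0.3, 0.3),
              gamma_range: tuple[float, float] = (0.0, 0.6),
              n_phi: int = 8, n_gamma: int = 9
              ) -> list[tuple[float, np.ndarray]]:
    """Coarse scan of the residual over (phi*, gamma1, gamma2).

    Returns feasible grid points sorted by residual norm; map failures
    (no contact, crashes, bad sequences) are simply skipped.
    """
    cfg = settings or SolverSettings()
    out: list[tuple[float, np.ndarray]] = []
    phis = np.linspace(*phi_range, n_phi)
    gammas = np.linspace(*gamma_range, n_gamma)
    for phi, g1, g2 in itertools.product(phis, gammas, gammas):
        w = np.array([phi, g1, g2])
        try:
            r, _ = residual(w, targets, p, cfg)
        except (SimulationError, EnergyInfeasibleError):
            continue
        out.append((float(np.linalg.norm(r)), w))
    out.sort(key=lambda t: t[0])
    return out


def find_solutions_at(y_star: float, thetadot_star: float, E: float,
                      p: ModelParameters,
                      settings: SolverSettings | None = None,
                      max_attempts: int = 30, **scan_kwargs
                      ) -> list[PeriodicSolution]:
    """All distinct symmetric periodic gaits at one (y*, thetadot*, E).

    Coarse grid scan followed by Newton polishing of the best-ranked
    seeds; duplicates are merged on the converged unknowns.
    """
    cfg = settings or SolverSettings()
    targets = (y_star, thetadot_star, E)
    seeds = grid_scan(targets, p, cfg, **scan_kwargs)
    found: list[PeriodicSolution] = []
    for _, w in seeds[:max_attempts]:
        try:
            sol = newton_solve(w, targets, p, cfg, mode="y")
        except ConvergenceError:
            continue
        if not any(sol.key() == s.key() for s in found):
            found.append(sol)
    return found


def _unknowns_y(sol: PeriodicSolution) -> np.ndarray:
    return np.array([sol.section.phi, sol.params.gamma1_td,
                     sol.params.gamma2_td])


#: half of the largest spine-joint excursion admitted in sweeps (rad):
#: solutions with |phi*| beyond pi/4 fold the trunk past a right angle,
#: far outside the posture range of galloping quadrupeds
PHI_LIMIT = math.pi / 4


def _continue_in_y(anchor: PeriodicSolution, thd: float, E: float,
                   y_grid: np.ndarray, p: ModelParameters,
                   cfg: SolverSettings, sweep: BranchSweep,
                   phi_limit: float = PHI_LIMIT) -> None:
    """Natural continuation in y* from an anchor, both directions.

    Seeds each step by secant extrapolation of the unknowns from the two
    previous solutions; on Newton failure retries once through the
    interval midpoint before declaring the family ended."""
    y0 = anchor.section.y
    for direction in (-1, 1):
        ys = sorted([y for y in y_grid if (y - y0) * direction > 1e-12],
                    key=lambda y: abs(y - y0))
        prev, prev2 = anchor, None
        for y in ys:
            if prev2 is not None and abs(prev.section.y - prev2.section.y) > 1e-12:
                frac = ((y - prev.section.y)
                        / (prev.section.y - prev2.section.y))
                seed = _unknowns_y(prev) + frac * (_unknowns_y(prev)
                                                  - _unknowns_y(prev2))
            else:
                seed = _unknowns_y(prev)
            try:
                sol = newton_solve(seed, (y, thd, E), p, cfg, mode="y")
            except ConvergenceError:
                try:
                    mid = newton_solve(_unknowns_y(prev),
                                       (0.5 * (prev.section.y + y), thd, E),
                                       p, cfg, mode="y")
                    sol = newton_solve(_unknowns_y(mid), (y, thd, E),
                                       p, cfg, mode="y")
                except ConvergenceError as exc:
                    sweep.failures.append((thd, y, str(exc)))
                    break
            if abs(sol.section.phi) > phi_limit:
                break
            sweep.add(sol)
            prev2, prev = prev, sol


def _unknowns_phi(sol: PeriodicSolution) -> np.ndarray:
    return np.array([sol.section.y, sol.params.gamma1_td,
                     sol.params.gamma2_td])


def _trace_in_phi(anchor: PeriodicSolution, thd: float, E: float,
                  y_lim: tuple[float, float], p: ModelParameters,
                  cfg: SolverSettings, dphi: float = 0.01,
                  max_steps: int = 250,
                  phi_limit: float = PHI_LIMIT) -> list[PeriodicSolution]:
    """Trace a folded family by continuation in phi*, both directions.

    phi* parameterizes folded families monotonically where y* does not.
    Steps are seeded by secant extrapolation; on failure the step is
    first halved (sharp turns) and finally enlarged (to leap across
    event-sequence boundaries where the map loses smoothness, e.g. the
    onset of double stance)."""
    traced = [anchor]
    for direction in (-1, 1):
        prev, prev2 = anchor, None
        steps_left = max_steps
        while steps_left > 0:
            steps_left -= 1
            advanced = False
            # halving handles sharp turns; enlarged steps leap across
            # event-sequence boundaries (e.g. double-stance onset) where
            # the map is continuous but not smooth
            for factor in (1.0, 0.5, 0.25, 0.125, 2.0, 4.0, 8.0, 12.0):
                step = direction * dphi * factor
                phi_next = prev.section.phi + step
                if abs(phi_next) > phi_limit:
                    continue
                if prev2 is not None and abs(prev.section.phi
                                             - prev2.section.phi) > 1e-12:
                    frac = step / (prev.section.phi - prev2.section.phi)
                    seed = _unknowns_phi(prev) + frac * (_unknowns_phi(prev)
                                                         - _unknowns_phi(prev2))
                else:
                    seed = _unknowns_phi(prev)
                try:
                    sol = newton_solve(seed, (phi_next, thd, E), p, cfg,
                                       mode="phi")
                except ConvergenceError:
                    continue
                advanced = True
                break
            if not advanced:
                break
            if not (y_lim[0] - 1e-9 <= sol.section.y <= y_lim[1] + 1e-9):
                break
            traced.append(sol)
            prev2, prev = prev, sol
    traced.sort(key=lambda s: s.section.phi)
    return traced


def _regrid_fold(traced: list[PeriodicSolution], thd: float, E: float,
                 y_grid: np.ndarray, p: ModelParameters, cfg: SolverSettings,
                 sweep: BranchSweep) -> None:
    """Re-solve a phi-traced folded family at grid y* values, one Newton
    solve per (grid point, monotone-in-y* leg of the fold)."""
    for s in traced:
        sweep.add(s)
    if len(traced) < 3:
        return
    ys = np.array([s.section.y for s in traced])
    turns = [0] + [i for i in range(1, len(ys) - 1)
                   if (ys[i] - ys[i - 1]) * (ys[i + 1] - ys[i]) < 0] \
        + [len(ys) - 1]
    legs = [traced[a:b + 1] for a, b in zip(turns[:-1], turns[1:])]
    for leg in legs:
        if len(leg) < 2:
            continue
        leg_ys = np.array([s.section.y for s in leg])
        lo, hi = leg_ys.min(), leg_ys.max()
        for y in y_grid:
            if not (lo <= y <= hi):
                continue
            nearest = leg[int(np.argmin(np.abs(leg_ys - y)))]
            seed = np.array([nearest.section.phi, nearest.params.gamma1_td,
                             nearest.params.gamma2_td])
            try:
                sol = newton_solve(seed, (y, thd, E), p, cfg, mode="y")
            except ConvergenceError as exc:
                sweep.failures.append((thd, y, f"fold regrid: {exc}"))
                continue
            sweep.add(sol)


def continuation_sweep(E: float, thetadot_values: Sequence[float],
                       y_range: tuple[float, float] = (0.60, 0.78),
                       p: ModelParameters | None = None,
                       settings: SolverSettings | None = None,
                       y_step: float = 0.005, anchor_y: float = 0.69,
                       with_floquet: bool = False) -> BranchSweep:
    """Trace all symmetric periodic families over a (y*, thetadot*) grid.

    For each apex pitch rate, anchors are found by a coarse scan at
    ``anchor_y``; families through each anchor are then continued in
    ``y*`` (and in ``phi*`` around folds, re-gridded back onto the
    ``y*`` grid so folded families yield their two solutions per apex
    height).  Per-point Newton failures are recorded, never raised.
    """
    p = p or ModelParameters()
    cfg = settings or SolverSettings()
    y_grid = np.round(np.arange(y_range[0], y_range[1] + 0.5 * y_step, y_step),
                      10)
    sweep = BranchSweep(E, tuple(thetadot_values), y_range)

    # -- anchor discovery, with fore-hind mirror seeding across +-thd --
    anchors: dict[float, list[PeriodicSolution]] = {}
    for thd in thetadot_values:
        anchors[thd] = find_solutions_at(anchor_y, thd, E, p, cfg)
        # the model is invariant under travel reversal: a solution at
        # -thd with swapped touchdown angles seeds one at +thd
        if -thd in anchors:
            for other in anchors[-thd]:
                seed = np.array([other.section.phi, other.params.gamma2_td,
                                 other.params.gamma1_td])
                try:
                    sol = newton_solve(seed, (other.section.y, thd, E),
                                       p, cfg, mode="y")
                except ConvergenceError:
                    continue
                if not any(sol.key() == a.key() for a in anchors[thd]):
                    anchors[thd].append(sol)
        # folded families cover a narrow y* band; if one branch label is
        # missing at anchor_y, look above and below
        for y_alt in (anchor_y + 0.03, anchor_y - 0.03):
            if len({a.branch for a in anchors[thd]}) >= 2:
                break
            for sol in find_solutions_at(y_alt, thd, E, p, cfg):
                if not any(sol.key() == a.key() for a in anchors[thd]):
                    anchors[thd].append(sol)

    for thd in thetadot_values:
        if not anchors[thd]:
            sweep.failures.append((thd, anchor_y, "no anchor solution found"))
            continue
        logger.info("thetadot*=%g: %d anchor(s): %s", thd, len(anchors[thd]),
                    [(a.branch, a.gait_type, round(a.section.phi, 3))
                     for a in anchors[thd]])
        for anchor in sorted(anchors[thd], key=lambda a: a.branch):
            if abs(anchor.section.phi) > PHI_LIMIT:
                continue
            if any(abs(anchor.section.phi - s.section.phi) < 5e-3
                   and abs(anchor.section.y - s.section.y) < 2e-3
                   for s in sweep.solutions
                   if s.section.thetadot == thd):
                continue  # anchor already covered by a traced family
            if anchor.branch == 1:
                sweep.add(anchor)
                _continue_in_y(anchor, thd, E, y_grid, p, cfg, sweep)
            else:
                traced = _trace_in_phi(anchor, thd, E, y_range, p, cfg)
                _regrid_fold(traced, thd, E, y_grid, p, cfg, sweep)
    if with_floquet:
        for sol in sweep.solutions:
            try:
                sol.floquet = floquet_eigenvalues(sol, p, cfg)
                sol.stable = _is_stable(sol.floquet)
            except ConvergenceError as exc:
                sweep.failures.append((sol.section.thetadot, sol.section.y,
                                       f"floquet: {exc}"))
    sweep.sort()
    return sweep


# --------------------------------------------------------------------- #
# Floquet stability

_COORD_IDX = (1, 2, 3, 4, 6, 7)   # y, theta, phi, xdot, thetadot, phidot


def _return_map_full(coords: np.ndarray, u: SearchParameters,
                     p: ModelParameters, cfg: SolverSettings) -> np.ndarray:
    """Apex-to-apex map on the 6 section coordinates
    (y, theta, phi, xdot, thetadot, phidot); x is quotiented out and
    ``ydot = 0`` defines the section."""
    s = np.zeros(8)
    s[list(_COORD_IDX)] = coords
    start = HybridState(
        ContinuousState(s[:4], s[4:], t=0.0),
        (LegState(1, LegMode.AIR, u.gamma1_td),
         LegState(2, LegMode.AIR, u.gamma2_td)))
    traj = simulate(start, p, stop="cycle", settings=cfg)
    end = traj.final_state().cont.vector
    return end[list(_COORD_IDX)]


def floquet_eigenvalues(sol: PeriodicSolution, p: ModelParameters,
                        settings: SolverSettings | None = None,
                        perturbation: float | None = None) -> np.ndarray:
    """Eigenvalues of the linearized apex return map at a fixed point.

    The linearization acts on the six apex coordinates
    ``(y, theta, phi, xdot, thetadot, phidot)`` with the horizontal
    position quotiented out; perturbed states carry their own perturbed
    energy, so the conserved energy contributes exactly one unit
    eigenvalue.  Eigenvalues are returned sorted by decreasing modulus.
    """
    cfg = settings or SolverSettings()
    delta = perturbation or cfg.floquet_delta
    z, u = sol.section, sol.params
    c0 = np.array([z.y, 0.0, z.phi, sol.xdot, z.thetadot, 0.0])
    f0 = _return_map_full(c0, u, p, cfg)
    J = np.empty((6, 6))
    for j in range(6):
        dj = delta
        for _ in range(6):
            cp = c0.copy()
            cp[j] += dj
            try:
                fj = _return_map_full(cp, u, p, cfg)
            except SimulationError:
                dj *= 0.5
                continue
            J[:, j] = (fj - f0) / dj
            break
        else:
            raise ConvergenceError(
                f"linearization failure in coordinate {j}")
    eig = np.linalg.eigvals(J)
    order = np.argsort(-np.abs(eig))
    return eig[order]


def _is_stable(eigenvalues: np.ndarray, unit_tol: float = 1e-3) -> bool:
    """All eigenvalues besides the single unit one inside the unit circle."""
    unit = int(np.argmin(np.abs(eigenvalues - 1.0)))
    rest = np.delete(eigenvalues, unit)
    return bool(np.all(np.abs(rest) < 1.0))
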
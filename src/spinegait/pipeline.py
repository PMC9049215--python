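"""End-to-end analysis pipeline: sweep, classify, measure, compare.

Runs the periodic-gait sweep at a fixed total energy, labels every
solution (type, branch, stability), computes the fluctuation and
impulse metrics, compares the characteristics with the packaged
measured-cheetah statistics, and writes reproducible CSV/JSON outputs.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import metrics as gm
from .params import ModelParameters, SolverSettings, load_config
from .reference import CHEETAH_REFERENCE, write_reference_table
from .search import BranchSweep, PeriodicSolution, continuation_sweep

__all__ = ["RunConfig", "run_pipeline", "solution_metrics", "metrics_table"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline configuration; the defaults reproduce the reference
    setting (E = 4500 J, apex pitch rates ±0.5 and ±1.5 rad/s)."""

    params: ModelParameters = field(default_factory=ModelParameters)
    solver: SolverSettings = field(default_factory=SolverSettings)
    energy: float = 4500.0
    thetadot_values: tuple[float, ...] = (-1.5, -0.5, 0.5, 1.5)
    y_min: float = 0.60
    y_max: float = 0.78
    y_step: float = 0.005
    anchor_y: float = 0.69
    with_floquet: bool = True
    outdir: Path = Path("spinegait_out")
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.y_min < self.y_max):
            raise ValueError("need 0 < y_min < y_max")
        if self.y_step <= 0 or self.energy <= 0:
            raise ValueError("y_step and energy must be positive")
        self.outdir = Path(self.outdir)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        params, solver, rest = load_config(path)
        kwargs = {k: v for k, v in rest.items()
                  if k in cls.__dataclass_fields__}
        unknown = set(rest) - set(kwargs)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "thetadot_values" in kwargs:
            kwargs["thetadot_values"] = tuple(kwargs["thetadot_values"])
        return cls(params=params, solver=solver, **kwargs)


def solution_metrics(sol: PeriodicSolution, p: ModelParameters) -> dict:
    """Flat metric record for one converged solution."""
    chars = gm.fluctuations(sol.trajectory)
    perf = gm.impulses(sol.trajectory, p)
    comparison = gm.compare_to_reference(
        gm.GaitCharacteristics(chars.delta_y, chars.delta_theta,
                               2.0 * chars.delta_phi),
        CHEETAH_REFERENCE)
    row = {
        "E": sol.params.E,
        "thetadot_star": sol.section.thetadot,
        "y_star": sol.section.y,
        "phi_star": sol.section.phi,
        "branch": sol.branch,
        "gait_type": sol.gait_type,
        "period": sol.period,
        "delta_y": chars.delta_y,
        "delta_theta": chars.delta_theta,
        "delta_phi_half": chars.delta_phi,          # model phi scale
        "delta_phi_joint": 2.0 * chars.delta_phi,   # spine joint (2 phi)
        "v_bar": perf.v_bar,
        "p_net": perf.p_net,
        "p1x_neg": perf.p1x_neg,
        "p1x_pos": perf.p1x_pos,
        "p2x_neg": perf.p2x_neg,
        "p2x_pos": perf.p2x_pos,
        "p_y": perf.p_y,
        "stance_spring_torque": gm.stance_spring_alignment(sol.trajectory, p),
        "residual_norm": sol.residual_norm,
        "energy_drift": sol.energy_drift,
        "max_abs_nontrivial_eigenvalue": sol.max_nontrivial_eigenvalue,
        "stable": sol.stable,
    }
    for name, rec in comparison.items():
        row[f"score_{name}"] = rec["score"]
    return row


def metrics_table(sweep: BranchSweep, p: ModelParameters) -> pd.DataFrame:
    return pd.DataFrame([solution_metrics(s, p) for s in sweep.solutions])


def _summary(sweep: BranchSweep, table: pd.DataFrame) -> dict:
    by_type = table.groupby("gait_type").size().to_dict() if len(table) else {}
    by_branch = table.groupby("branch").size().to_dict() if len(table) else {}
    out = {
        "energy": sweep.energy,
        "thetadot_values": list(sweep.thetadot_values),
        "n_solutions": len(sweep.solutions),
        "n_failures": len(sweep.failures),
        "types": {str(k): int(v) for k, v in by_type.items()},
        "branches": {str(int(k)): int(v) for k, v in by_branch.items()},
    }
    if len(table):
        out["v_bar_range"] = [float(table["v_bar"].min()),
                              float(table["v_bar"].max())]
        stable = table[table["stable"] == True]  # noqa: E712
        out["n_stable"] = int(len(stable))
        if len(stable):
            out["stable_types"] = sorted(stable["gait_type"].unique())
            out["stable_y_star_range"] = [float(stable["y_star"].min()),
                                          float(stable["y_star"].max())]
    return out


def _summary_text(s: dict) -> str:
    lines = [
        f"energy: {s['energy']} J",
        f"apex pitch rates: {s['thetadot_values']} rad/s",
        f"solutions: {s['n_solutions']} ({s['n_failures']} grid failures)",
        "types: " + ", ".join(f"{k}={v}" for k, v in sorted(s["types"].items())),
        "branches: " + ", ".join(f"{k}={v}"
                                 for k, v in sorted(s["branches"].items())),
    ]
    if "v_bar_range" in s:
        lines.append("average velocity range: "
                     f"{s['v_bar_range'][0]:.3f}-{s['v_bar_range'][1]:.3f} m/s")
    if s.get("n_stable"):
        lines.append(f"stable solutions: {s['n_stable']} "
                     f"(types {', '.join(s['stable_types'])}; "
                     f"y* in {s['stable_y_star_range'][0]:.3f}-"
                     f"{s['stable_y_star_range'][1]:.3f} m)")
    return "\n".join(lines) + "\n"


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full sweep → classify → metrics → comparison chain.

    Writes ``solutions.csv``, ``metrics.csv``, ``comparison.csv``,
    ``reference.json``, ``summary.json`` and ``summary.txt`` under
    ``cfg.outdir`` and returns the summary dict.  Rows with energy
    drift above tolerance are never emitted as converged.
    """
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    sweep = continuation_sweep(
        cfg.energy, cfg.thetadot_values, (cfg.y_min, cfg.y_max),
        p=cfg.params, settings=cfg.solver, y_step=cfg.y_step,
        anchor_y=cfg.anchor_y, with_floquet=cfg.with_floquet)

    bad = [s for s in sweep.solutions
           if s.energy_drift is not None
           and s.energy_drift > cfg.solver.energy_tol]
    for s in bad:
        logger.error("dropping solution at (y*=%.3f, thd*=%.2f): "
                     "energy drift %.2e", s.section.y, s.section.thetadot,
                     s.energy_drift)
        sweep.failures.append((s.section.thetadot, s.section.y,
                               f"energy drift {s.energy_drift:.2e}"))
    sweep.solutions = [s for s in sweep.solutions if s not in bad]

    table = metrics_table(sweep, cfg.params)
    sweep.to_dataframe().to_csv(cfg.outdir / "solutions.csv", index=False)
    table.to_csv(cfg.outdir / "metrics.csv", index=False)
    if len(table):
        comp_cols = ["thetadot_star", "y_star", "branch", "gait_type",
                     "delta_y", "delta_theta", "delta_phi_joint",
                     "score_delta_y", "score_delta_theta", "score_delta_phi"]
        table[comp_cols].to_csv(cfg.outdir / "comparison.csv", index=False)
    write_reference_table(cfg.outdir / "reference.json")

    summary = _summary(sweep, table)
    (cfg.outdir / "summary.json").write_text(
        json.dumps(summary, indent=2) + "\n")
    (cfg.outdir / "summary.txt").write_text(_summary_text(summary))
    return summary
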
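"""Physical parameters of the two-body galloping model.

The model is a sagittal-plane bounding template: two identical rigid
bodies (fore and hind halves of the trunk) coupled by a torsional spine
spring, each carrying one massless prismatic spring leg.  Parameter
defaults are scaled to an adult cheetah (≈38 kg whole body).
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["ModelParameters", "SolverSettings", "load_config"]


@dataclass(frozen=True)
class ModelParameters:
    """Physical constants of the planar two-body model.

    Attributes
    ----------
    m : float
        Mass of each half body (kg).
    J : float
        Pitch moment of inertia of each half body about its own COM (kg m^2).
    r : float
        Half length of each body segment (m); segment length is ``2 r``.
    d : float
        Distance from a body COM to its leg joint (m), positive when the
        leg joint lies outside the COM relative to the spine joint.
    l0 : float
        Nominal (rest) leg length (m); legs keep this length in the air.
    k : float
        Leg spring constant (N/m).
    kt : float
        Torsional spine spring constant (N m/rad); the spring is relaxed
        when the two bodies are collinear.
    g : float
        Gravitational acceleration (m/s^2).
    """

    m: float = 19.0
    J: float = 0.53
    r: float = 0.29
    d: float = 0.06
    l0: float = 0.69
    k: float = 15000.0
    kt: float = 100.0
    g: float = 9.81

    def __post_init__(self) -> None:
        for name in ("m", "J", "r", "l0", "k", "kt", "g"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"parameter {name!r} must be strictly positive")

    @property
    def hip_offset(self) -> float:
        """Distance from the whole-body COM to each leg joint along the
        COM–COM line, ``r + d`` (m)."""
        return self.r + self.d

    @property
    def total_mass(self) -> float:
        """Whole-body mass ``2 m`` (kg)."""
        return 2.0 * self.m

    def replace(self, **changes: float) -> "ModelParameters":
        return replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "ModelParameters":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown model parameters: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in data.items()})


@dataclass(frozen=True)
class SolverSettings:
    """Numerical settings for event-driven integration and root finding.

    rtol/atol control the adaptive integrator; energy drift over a cycle
    is the practical accuracy surface and sits orders of magnitude below
    ``energy_tol`` at the defaults.
    """

    rtol: float = 1e-10
    atol: float = 1e-10
    energy_tol: float = 1e-8          # max allowed relative energy drift
    horizon: float = 3.0              # max simulated time per cycle (s)
    newton_tol: float = 1e-10         # Newton residual norm tolerance
    newton_max_iter: int = 50
    newton_fd_step: float = 1e-7      # forward-difference Jacobian step
    grazing_tol: float = 1e-9         # min stance duration (s)
    floquet_delta: float = 1e-6       # finite-difference perturbation scale

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "SolverSettings":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown solver settings: {sorted(unknown)}")
        kwargs: dict[str, Any] = dict(data)
        if "newton_max_iter" in kwargs:
            kwargs["newton_max_iter"] = int(kwargs["newton_max_iter"])
        return cls(**kwargs)


def load_config(path: str | Path) -> tuple[ModelParameters, SolverSettings, dict]:
    """Read a flat YAML config with optional ``model`` and ``solver``
    sections; remaining top-level keys are returned verbatim."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    params = ModelParameters.from_dict(raw.pop("model", {}))
    solver = SolverSettings.from_dict(raw.pop("solver", {}))
    return params, solver, raw
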
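"""Synthetic marker strides and marker-based characteristic extraction.

Bridges the model to the way the measured cheetah statistics are
defined: five sagittal-plane anatomical markers (neck root, T12 —
the twelfth thoracic vertebra at the spine joint — tail root, shoulder,
greater trochanter), from which

* ``delta_y``  is the height fluctuation of the shoulder–trochanter
  midpoint,
* ``delta_theta`` the fluctuation of the pitch of the neck-root →
  tail-root line, and
* ``delta_phi`` the fluctuation of the relative angle between the
  neck-root → T12 and T12 → tail-root lines (the anatomical
  inter-segment angle, i.e. the model joint angle ``2 phi``).

The synthetic generator emulates one gallop stride of such marker data
with single-harmonic height/pitch/spine signals of controllable
amplitude plus optional Gaussian marker noise; it is the stand-in for
motion-capture input and carries its ground truth along.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import GaitCharacteristics, fluctuations
from .params import ModelParameters

__all__ = [
    "MARKER_NAMES", "MarkerStride", "skeleton_markers", "synth_stride",
    "markers_from_solution", "extract_characteristics",
]

MARKER_NAMES = ("neck_root", "T12", "tail_root", "shoulder", "trochanter")


@dataclass
class MarkerStride:
    """Timestamped 2D positions of the five markers over >= 1 stride.

    ``truth`` (synthetic strides only) holds the generating
    characteristics, with ``delta_phi`` on the inter-segment-angle
    scale."""

    t: np.ndarray
    positions: dict[str, np.ndarray]          # name -> (N, 2)
    truth: GaitCharacteristics | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if self.t.ndim != 1 or len(self.t) < 2:
            raise ValueError("need a 1-D time grid with >= 2 samples")
        dt = np.diff(self.t)
        if not (np.all(dt > 0) and np.allclose(dt, dt[0], rtol=1e-6)):
            raise ValueError("time grid must be uniform and increasing")
        missing = set(MARKER_NAMES) - set(self.positions)
        if missing:
            raise ValueError(f"missing markers: {sorted(missing)}")
        for name in MARKER_NAMES:
            arr = np.asarray(self.positions[name], dtype=float)
            if arr.shape != (len(self.t), 2):
                raise ValueError(f"marker {name!r} must be (N, 2)")
            self.positions[name] = arr

    def to_csv(self, path: str | Path) -> None:
        """Long-form CSV: columns t, marker, x, y."""
        rows = []
        for name in MARKER_NAMES:
            arr = self.positions[name]
            for t, (x, y) in zip(self.t, arr):
                rows.append((t, name, x, y))
        pd.DataFrame(rows, columns=["t", "marker", "x", "y"]).to_csv(
            path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "MarkerStride":
        df = pd.read_csv(path)
        required = {"t", "marker", "x", "y"}
        if not required <= set(df.columns):
            raise ValueError(f"marker CSV needs columns {sorted(required)}")
        ts = np.sort(df["t"].unique())
        positions = {}
        for name, grp in df.groupby("marker"):
            grp = grp.sort_values("t")
            positions[str(name)] = grp[["x", "y"]].to_numpy(float)
        return cls(ts, positions)


def skeleton_markers(x: np.ndarray, y: np.ndarray, theta: np.ndarray,
                     phi: np.ndarray, p: ModelParameters
                     ) -> dict[str, np.ndarray]:
    """Marker positions from COM pose channels and body geometry.

    The two body segments (length ``2 r`` each) meet at the spine joint
    (T12) with half angle ``phi``; body 2 leads in +x.  Free ends are
    the neck root (body 2) and tail root (body 1); leg joints sit a
    distance ``d`` beyond each body COM along that body's axis
    (shoulder on body 2, greater trochanter on body 1), matching the
    model's hip placement.
    """
    x, y, theta, phi = (np.asarray(a, dtype=float) for a in (x, y, theta, phi))
    cthcph = np.cos(theta) * np.cos(phi)
    sthcph = np.sin(theta) * np.cos(phi)
    com = np.stack([x, y], axis=-1)
    axis = np.stack([cthcph, sthcph], axis=-1)
    c1 = com - p.r * axis
    c2 = com + p.r * axis
    psi1, psi2 = theta - phi, theta + phi
    u1 = np.stack([np.cos(psi1), np.sin(psi1)], axis=-1)
    u2 = np.stack([np.cos(psi2), np.sin(psi2)], axis=-1)
    return {
        "T12": c1 + p.r * u1,                 # == c2 - r u2
        "tail_root": c1 - p.r * u1,
        "neck_root": c2 + p.r * u2,
        "trochanter": c1 - p.d * u1,
        "shoulder": c2 + p.d * u2,
    }


def synth_stride(amplitudes: tuple[float, float, float] = (0.0285, 0.10, 0.235),
                 stride: float = 0.32,
                 baseline: ModelParameters | None = None,
                 noise_sd: float = 0.0,
                 seed: int | None = None,
                 n_samples: int = 101,
                 speed: float = 15.0,
                 y0: float = 0.69) -> MarkerStride:
    """One synthetic gallop stride of five-marker data.

    The COM-proxy height (shoulder–trochanter midpoint), whole-body
    pitch and inter-segment spine angle follow single harmonics of
    amplitudes ``(A_y, A_theta, A_phi)`` (peak-to-peak fluctuation,
    hence ground truth, is ``2 A`` per channel), with fixed phase
    offsets between channels as in a gallop (spine leads pitch by a
    quarter cycle).  The underlying COM height compensates the hip
    offset so the proxy height is exactly harmonic.  i.i.d. Gaussian
    noise of standard deviation ``noise_sd`` is added to every marker
    coordinate.  Deterministic for a given seed.
    """
    a_y, a_th, a_ph = amplitudes
    if min(a_y, a_th, a_ph) < 0:
        raise ValueError("amplitudes must be non-negative")
    if stride <= 0:
        raise ValueError("stride duration must be positive")
    p = baseline or ModelParameters()
    t = np.linspace(0.0, stride, n_samples)
    w = 2.0 * math.pi / stride
    x = speed * t
    height = y0 + a_y * np.sin(w * t)
    theta = a_th * np.sin(w * t + 0.5 * math.pi)
    # the anatomical inter-segment angle is 2 phi
    phi = 0.5 * a_ph * np.sin(w * t + math.pi)
    # shoulder-trochanter midpoint sits d*cos(theta)*sin(phi) above the
    # COM; shift the COM so the proxy height is the prescribed harmonic
    y = height - p.d * np.cos(theta) * np.sin(phi)
    positions = skeleton_markers(x, y, theta, phi, p)
    if noise_sd > 0.0:
        rng = np.random.default_rng(seed)
        for name in MARKER_NAMES:
            positions[name] = positions[name] + rng.normal(
                0.0, noise_sd, positions[name].shape)
    truth = GaitCharacteristics(2.0 * a_y, 2.0 * a_th, 2.0 * a_ph)
    return MarkerStride(t, positions, truth=truth, seed=seed)


def markers_from_solution(sol, p: ModelParameters | None = None,
                          n_samples: int = 401) -> MarkerStride:
    """Marker stride generated from a converged periodic solution.

    Ground truth carries the model's own cycle fluctuations, with the
    spine channel mapped to the inter-segment scale (``2 phi``).
    """
    traj = sol.trajectory
    p = p or traj.params
    df = traj.sample(n_samples)
    positions = skeleton_markers(df["x"].to_numpy(), df["y"].to_numpy(),
                                 df["theta"].to_numpy(), df["phi"].to_numpy(),
                                 p)
    chars = fluctuations(traj, n=max(2001, n_samples))
    truth = GaitCharacteristics(chars.delta_y, chars.delta_theta,
                                2.0 * chars.delta_phi)
    return MarkerStride(df["t"].to_numpy() - df["t"].iloc[0], positions,
                        truth=truth)


def _line_angle(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Unwrapped angle of the a -> b line over the stride."""
    d = b - a
    return np.unwrap(np.arctan2(d[:, 1], d[:, 0]))


def extract_characteristics(stride: MarkerStride,
                            lowpass_hz: float | None = None
                            ) -> GaitCharacteristics:
    """Marker-based gait characteristics of one stride.

    * ``delta_y``: max - min height of the shoulder–trochanter midpoint
      (frame dependent: heights are measured along the lab +y axis);
    * ``delta_theta``: max - min of the neck-root → tail-root line
      angle (full-quadrant, unwrapped);
    * ``delta_phi``: max - min of the relative angle between the
      neck-root → T12 and T12 → tail-root lines (inter-segment scale).

    ``lowpass_hz`` applies a zero-phase 4th-order Butterworth low-pass
    to every marker coordinate first.  Raw max - min ranges are biased
    upward by measurement noise, so noisy data should be filtered; a
    cutoff of about six times the stride frequency keeps the gait
    harmonics while suppressing most of the noise band.
    """
    pos = stride.positions
    if lowpass_hz is not None:
        from scipy.signal import butter, filtfilt
        fs = 1.0 / (stride.t[1] - stride.t[0])
        if not 0.0 < lowpass_hz < 0.5 * fs:
            raise ValueError("lowpass cutoff must lie below the Nyquist rate")
        b, a = butter(4, lowpass_hz / (0.5 * fs))
        pos = {k: filtfilt(b, a, v, axis=0) for k, v in pos.items()}
    mid_y = 0.5 * (pos["shoulder"][:, 1] + pos["trochanter"][:, 1])
    delta_y = float(mid_y.max() - mid_y.min())
    pitch = _line_angle(pos["neck_root"], pos["tail_root"])
    delta_theta = float(pitch.max() - pitch.min())
    a1 = _line_angle(pos["neck_root"], pos["T12"])
    a2 = _line_angle(pos["T12"], pos["tail_root"])
    rel = np.unwrap(a2 - a1)
    delta_phi = float(rel.max() - rel.min())
    return GaitCharacteristics(delta_y, delta_theta, delta_phi)
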
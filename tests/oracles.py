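"""Independent numerical oracles shared by the test modules.

Everything here is written from first principles (energy expressions and
finite differences only) so it cannot inherit a mistake from the package
implementation it checks.
"""
from __future__ import annotations

import math

import numpy as np

from spinegait.model import LegMode, leg_length


def lagrangian_accelerations(q, qd, legs, p):
    """Generalized accelerations from a finite-difference Euler-Lagrange
    evaluation of the model's kinetic and potential energy."""

    def kinetic(q_, qd_):
        c2, s2 = math.cos(q_[3]) ** 2, math.sin(q_[3]) ** 2
        return (p.m * (qd_[0] ** 2 + qd_[1] ** 2)
                + (p.J + p.m * p.r ** 2 * c2) * qd_[2] ** 2
                + (p.J + p.m * p.r ** 2 * s2) * qd_[3] ** 2)

    def potential(q_):
        e = 2 * p.m * p.g * q_[1] + 2 * p.kt * q_[3] ** 2
        for leg in legs:
            if leg.mode is LegMode.STANCE:
                e += 0.5 * p.k * (p.l0 - leg_length(q_, leg, p)) ** 2
        return e

    L = lambda q_, qd_: kinetic(q_, qd_) - potential(q_)
    hv, hq, hg = 1e-2, 1e-4, 1e-3
    H = np.zeros((4, 4))   # d2L/dqd dqd (exact: L quadratic in qd)
    C = np.zeros((4, 4))   # d2L/dqd dq
    gq = np.zeros(4)       # dL/dq, 4th-order stencil
    for i in range(4):
        ei = np.eye(4)[i]
        gq[i] = (L(q - 2 * hg * ei, qd) - 8 * L(q - hg * ei, qd)
                 + 8 * L(q + hg * ei, qd) - L(q + 2 * hg * ei, qd)
                 ) / (12 * hg)
        for j in range(4):
            ej = np.eye(4)[j]
            H[i, j] = (L(q, qd + hv * (ei + ej)) - L(q, qd + hv * (ei - ej))
                       - L(q, qd - hv * (ei - ej)) + L(q, qd - hv * (ei + ej))
                       ) / (4 * hv * hv)
            C[i, j] = (L(q + hq * ej, qd + hv * ei)
                       - L(q + hq * ej, qd - hv * ei)
                       - L(q - hq * ej, qd + hv * ei)
                       + L(q - hq * ej, qd - hv * ei)) / (4 * hv * hq)
    return np.linalg.solve(H, gq - C @ qd)


def random_hybrid_states(p, rng, n):
    """Physically valid random states: any leg in stance is compressed."""
    from spinegait.model import (ContinuousState, HybridState, LegState,
                                 hip_position)
    out = []
    while len(out) < n:
        q = np.array([rng.normal(0, 0.5), rng.uniform(0.45, 0.9),
                      rng.uniform(-0.4, 0.4), rng.uniform(-0.4, 0.4)])
        qd = rng.normal(0, 2.0, 4)
        modes = rng.integers(0, 2, 2)
        legs = []
        for i in (1, 2):
            if modes[i - 1]:
                hx, hy = hip_position(q, i, p)
                gamma = rng.uniform(-0.3, 0.3)
                legs.append(LegState(i, LegMode.STANCE, gamma_td=gamma,
                                     toe_x=hx + hy * math.tan(gamma)))
            else:
                legs.append(LegState(i, LegMode.AIR, 0.2))
        legs = tuple(legs)
        if any(l.mode is LegMode.STANCE and leg_length(q, l, p) > p.l0
               for l in legs):
            continue
        out.append(HybridState(ContinuousState(q, qd), legs))
    return out
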
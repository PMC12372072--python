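"""Independent numerical oracles used to cross-check the implementation.

These deliberately take different routes than the package: the chain
dynamics via an unreduced differential-algebraic (Lagrange-multiplier)
formulation solved as a 3x3 linear system, DTW via a plain full-matrix
dynamic program, and the equilibrium torque via numerical differentiation
of the gravitational potential.
"""

from __future__ import annotations

import math

import numpy as np


def dae_acceleration(theta1, theta1_dot, tau1, tau2, chain, d):
    """(theta1_ddot, theta2_ddot, Rx) from the unreduced constrained system.

    Both links are treated as free generalized coordinates (theta1, theta2)
    with the track constraint g = l1 cos th1 + l2 cos th2 - d = 0 enforced
    through a Lagrange multiplier, which is exactly the horizontal track
    reaction.  Euler-Lagrange equations of the two-link chain with the
    generalized muscle forces Q1 = tau1 - tau2, Q2 = tau2.
    """
    l1, l2, lC2 = chain.l1, chain.l2, chain.lC2
    m1, m2, g = chain.m1, chain.m2, chain.g
    I1, I2 = chain.I1, chain.I2
    c2v = (d - l1 * math.cos(theta1)) / l2
    theta2 = math.acos(min(1.0, max(-1.0, c2v)))
    s1, c1 = math.sin(theta1), math.cos(theta1)
    s2, c2 = math.sin(theta2), math.cos(theta2)
    theta2_dot = -(l1 * s1) / (l2 * s2) * theta1_dot
    Delta = theta2 - theta1
    cD, sD = math.cos(Delta), math.sin(Delta)
    h = m2 * l1 * lC2

    M = np.array(
        [
            [I1 + m2 * l1**2, h * cD, l1 * s1],
            [h * cD, I2, l2 * s2],
            [-l1 * s1, -l2 * s2, 0.0],
        ]
    )
    dV1 = (m1 * chain.lC1 + m2 * l1) * g * c1
    dV2 = m2 * g * lC2 * c2
    rhs = np.array(
        [
            (tau1 - tau2) - dV1 + h * theta2_dot**2 * sD,
            tau2 - dV2 - h * theta1_dot**2 * sD,
            l1 * c1 * theta1_dot**2 + l2 * c2 * theta2_dot**2,
        ]
    )
    th1dd, th2dd, lam = np.linalg.solve(M, rhs)
    return float(th1dd), float(th2dd), float(lam)


def dae_rhs(t, y, tau1, tau2, chain, d):
    """ODE right-hand side built on the DAE oracle, for trajectory checks."""
    th1dd, _, _ = dae_acceleration(y[0], y[1], tau1, tau2, chain, d)
    return [y[1], th1dd]


def potential_energy(theta1, chain, d):
    """Gravitational potential of the constrained chain as V(theta1)."""
    l1, l2 = chain.l1, chain.l2
    c2 = (d - l1 * np.cos(theta1)) / l2
    s2 = np.sqrt(1.0 - c2**2)
    return chain.m1 * chain.g * chain.lC1 * np.sin(theta1) + chain.m2 * chain.g * (
        l1 * np.sin(theta1) + chain.lC2 * s2
    )


def kinetic_energy(theta1, theta1_dot, chain, d):
    """Kinetic energy of the constrained chain at (theta1, theta1_dot)."""
    l1, l2, lC2 = chain.l1, chain.l2, chain.lC2
    c2v = (d - l1 * np.cos(theta1)) / l2
    theta2 = np.arccos(np.clip(c2v, -1.0, 1.0))
    s2 = np.sin(theta2)
    theta2_dot = -(l1 * np.sin(theta1)) / (l2 * s2) * theta1_dot
    Delta = theta2 - theta1
    return (
        0.5 * (chain.I1 + chain.m2 * l1**2) * theta1_dot**2
        + 0.5 * chain.I2 * theta2_dot**2
        + chain.m2 * l1 * lC2 * theta1_dot * theta2_dot * np.cos(Delta)
    )


def equilibrium_torque_virtual_work(theta1, chain, d, h=1e-6):
    """tau1 balancing gravity, via a 4th-order stencil of -dV/dtheta1...

    ...with the sign flipped: at equilibrium the muscle torque equals
    +dV/dtheta1 (it must push against gravity's generalized force -dV/dq).
    """
    V = lambda th: potential_energy(th, chain, d)
    dV = (-V(theta1 + 2 * h) + 8 * V(theta1 + h) - 8 * V(theta1 - h) + V(theta1 - 2 * h)) / (12 * h)
    return dV


def dtw_bruteforce(a, b):
    """Unconstrained DTW distance by the plain full-matrix recursion."""
    a = list(map(float, a))
    b = list(map(float, b))
    n, m = len(a), len(b)
    INF = float("inf")
    D = [[INF] * m for _ in range(n)]
    for i in range(n):
        for j in range(m):
            c = abs(a[i] - b[j])
            if i == 0 and j == 0:
                D[i][j] = c
                continue
            best = INF
            if i > 0:
                best = min(best, D[i - 1][j])
            if j > 0:
                best = min(best, D[i][j - 1])
            if i > 0 and j > 0:
                best = min(best, D[i - 1][j - 1])
            D[i][j] = c + best
    return D[n - 1][m - 1]


def muscle_moment_bruteforce(points, vectors, about):
    """Sum of planar moments of point forces about a pivot (z-component)."""
    total = 0.0
    for P, F in zip(points, vectors):
        r = np.asarray(P, dtype=float) - np.asarray(about, dtype=float)
        F = np.asarray(F, dtype=float)
        total += float(r[0] * F[1] - r[1] * F[0])
    return total
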
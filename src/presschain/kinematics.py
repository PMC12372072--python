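"""Constraint kinematics of the closed chain.

The vertical barbell track imposes ``l1*cos(theta1) + l2*cos(theta2) = d``,
reducing the chain to one degree of freedom.  All maps here are exact
trigonometric identities: the elbow angle and its rates, the endpoint
height/velocity, rigid-body point accelerations, and the inverse
height-to-angle map used for plotting against yP.

Conventions: J1 at the origin, x horizontal toward the track, y vertical
up, angles measured counter-clockwise from horizontal.  The non-negative
``sin(theta2)`` branch is fixed throughout (the endpoint stays above the
elbow's horizontal in both exercises); configurations with link 2
horizontal (``sin(theta2) = 0``) are singular and raise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .model import ChainParams

_RESIDUAL_TOL = 1e-9


class ConstraintError(ValueError):
    """Shoulder angle incompatible with the barbell constraint."""


class SingularConfigurationError(ValueError):
    """Link 2 horizontal: the constraint Jacobian vanishes."""


def solve_theta2(theta1, chain: ChainParams, d: float):
    """Elbow-link angle theta2 in [0, pi] satisfying the track constraint.

    ``cos(theta2) = (d - l1*cos(theta1))/l2`` with the non-negative
    ``sin(theta2)`` branch.  Accepts scalars or arrays.
    """
    c2 = (d - chain.l1 * np.cos(theta1)) / chain.l2
    if np.any(np.abs(c2) > 1.0 + 1e-12):
        raise ConstraintError("theta1 infeasible: |d - l1*cos(theta1)| > l2")
    c2 = np.clip(c2, -1.0, 1.0)
    return np.arccos(c2)


def lockout_angle(chain: ChainParams, d: float) -> float:
    """Shoulder angle at full elbow extension, arccos(d/(l1+l2))."""
    if not 0.0 < d < chain.reach:
        raise ConstraintError("d outside (0, l1+l2)")
    return math.acos(d / chain.reach)


def feasible_theta1_range(chain: ChainParams, d: float) -> tuple[float, float]:
    """Open interval of shoulder angles compatible with the constraint.

    The lower end is where the elbow link goes horizontal pointing back
    (``cos(theta2) = 1``, singular) or -pi/2; the upper end is lockout.
    """
    c1_min = (d - chain.l2) / chain.l1
    lo = -0.5 * math.pi if c1_min < -1.0 else -math.acos(min(c1_min, 1.0))
    return lo, lockout_angle(chain, d)


@dataclass(frozen=True)
class ChainState:
    """Kinematic state of the chain at one instant.

    ``theta2``, ``theta2_dot``, ``yP`` and ``yP_dot`` are derived from
    ``(theta1, theta1_dot)`` through the constraint at construction time.
    """

    theta1: float
    theta1_dot: float
    theta2: float
    theta2_dot: float
    yP: float
    yP_dot: float
    t: float = 0.0

    @classmethod
    def from_theta1(
        cls, theta1: float, theta1_dot: float, chain: ChainParams, d: float, t: float = 0.0
    ) -> "ChainState":
        theta2 = float(solve_theta2(theta1, chain, d))
        s2 = math.sin(theta2)
        if s2 < 1e-12:
            raise SingularConfigurationError("sin(theta2) = 0")
        theta2_dot = -(chain.l1 * math.sin(theta1)) / (chain.l2 * s2) * theta1_dot
        yP = chain.l1 * math.sin(theta1) + chain.l2 * s2
        yP_dot = chain.l1 * math.cos(theta1) * theta1_dot + chain.l2 * math.cos(theta2) * theta2_dot
        residual = chain.l1 * math.cos(theta1) + chain.l2 * math.cos(theta2) - d
        if abs(residual) > _RESIDUAL_TOL:
            raise ConstraintError(f"constraint residual {residual:.2e} m")
        if theta2 < theta1 - 1e-9:
            raise ConstraintError("elbow hyperextended (theta2 < theta1)")
        return cls(theta1, theta1_dot, theta2, theta2_dot, yP, yP_dot, t)


def constraint_derivatives(state: ChainState, chain: ChainParams) -> tuple[float, float, float]:
    """Constraint rate maps at ``state``: (dtheta2/dtheta1, B, C).

    ``dtheta2/dtheta1 = -(l1 sin th1)/(l2 sin th2)`` and the acceleration
    relation ``theta2_ddot = B*theta1_ddot + C*theta1_dot^2`` with ``B``
    equal to the same ratio and ``C`` collecting the velocity-squared terms
    of the twice-differentiated constraint.
    """
    s1, c1 = math.sin(state.theta1), math.cos(state.theta1)
    s2, c2 = math.sin(state.theta2), math.cos(state.theta2)
    l1, l2 = chain.l1, chain.l2
    if abs(s2) < 1e-12:
        raise SingularConfigurationError("sin(theta2) = 0")
    B = -(l1 * s1) / (l2 * s2)
    C = -(l1 * c1) / (l2 * s2) - (l1 * s1) ** 2 * c2 / (l2**2 * s2**3)
    return B, B, C


def endpoint_state(state: ChainState, chain: ChainParams, d: float) -> tuple[float, float]:
    """(yP, yP_dot) of the barbell endpoint; identical to the state fields."""
    return state.yP, state.yP_dot


def endpoint_height(theta1, chain: ChainParams, d: float):
    """Barbell height yP(theta1) = l1 sin th1 + l2 sin th2 (vectorised)."""
    theta2 = solve_theta2(theta1, chain, d)
    return chain.l1 * np.sin(theta1) + chain.l2 * np.sin(theta2)


def max_height(chain: ChainParams, d: float) -> float:
    """Lockout barbell height sqrt((l1+l2)^2 - d^2)."""
    return math.sqrt(chain.reach**2 - d**2)


def _unit_vectors(theta: float) -> tuple[np.ndarray, np.ndarray]:
    u = np.array([math.cos(theta), math.sin(theta)])
    w = np.array([-math.sin(theta), math.cos(theta)])  # k x u
    return u, w


def point_accelerations(
    state: ChainState, theta1_ddot: float, chain: ChainParams
) -> tuple[np.ndarray, np.ndarray]:
    """Planar accelerations (a_J2, a_C2) for a given shoulder acceleration.

    The elbow acceleration follows from the constraint; rigid-body
    composition gives ``a = th_ddot*l*w_hat - th_dot^2*l*u_hat`` terms
    across the two links.
    """
    B, _, C = constraint_derivatives(state, chain)
    theta2_ddot = B * theta1_ddot + C * state.theta1_dot**2
    u1, w1 = _unit_vectors(state.theta1)
    u2, w2 = _unit_vectors(state.theta2)
    a_J2 = theta1_ddot * chain.l1 * w1 - state.theta1_dot**2 * chain.l1 * u1
    a_C2 = a_J2 + theta2_ddot * chain.lC2 * w2 - state.theta2_dot**2 * chain.lC2 * u2
    return a_J2, a_C2


def com_acceleration_link1(state: ChainState, theta1_ddot: float, chain: ChainParams) -> np.ndarray:
    """Acceleration of C1, the centre of mass of the upper arm."""
    u1, w1 = _unit_vectors(state.theta1)
    return theta1_ddot * chain.lC1 * w1 - state.theta1_dot**2 * chain.lC1 * u1


def theta1_of_height(yP: float, chain: ChainParams, d: float) -> float:
    """Invert yP(theta1) on the lift branch by bracketed root finding.

    yP is strictly increasing between the feasible minimum and lockout, so
    the root is unique; resolution 1e-12 rad (height residual < 1e-9 m).
    """
    lo, hi = feasible_theta1_range(chain, d)
    lo += 1e-9
    y_lo = endpoint_height(lo, chain, d)
    y_hi = max_height(chain, d)
    if not (y_lo - 1e-9 <= yP <= y_hi + 1e-9):
        raise ValueError(f"yP={yP:.4f} outside reachable range [{y_lo:.4f}, {y_hi:.4f}]")
    if yP >= y_hi:
        return hi
    return brentq(lambda th: endpoint_height(th, chain, d) - yP, lo, hi, xtol=1e-12)
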
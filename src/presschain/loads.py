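"""Track reaction and joint reaction forces, with optional muscle force sets.

The horizontal track reaction follows from the moment balance of link 2:

    Rx = [tau2 - m2*g*lC2*c2 - I2*th2dd
          - m2*lC2*l1*(th1dd*cos(D) + th1d^2*sin(D))] / (l2*s2)

(D = theta2 - theta1).  Newton balances of link 2 and of the whole chain
then give the elbow reaction phi21 and the shoulder reaction phi10.  Muscle
forces are user-supplied point forces; the default empty set yields the
reactions of an ideal torque generator.  All vectors are planar (x, y) in
the global frame, newtons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .kinematics import (
    ChainState,
    com_acceleration_link1,
    constraint_derivatives,
    point_accelerations,
)
from .model import ChainParams


@dataclass(frozen=True)
class MuscleForce:
    """A muscle modelled as a point force on one link.

    ``origin_link``/``insertion_link`` identify the links the muscle
    connects (0 = base/trunk, 1 = upper arm, 2 = forearm+hand); the force
    acts on ``insertion_link`` at ``point`` given in that link's local
    frame (along-axis, normal) metres from its proximal joint, with the
    force ``vector`` in the global frame.  The equal-and-opposite pull on
    the origin link is implied.
    """

    label: str
    origin_link: int
    insertion_link: int
    point: tuple[float, float]
    vector: tuple[float, float]

    def __post_init__(self) -> None:
        if self.insertion_link not in (1, 2):
            raise ValueError("forces are applied on link 1 or link 2")
        if self.origin_link == self.insertion_link:
            raise ValueError("origin and insertion links must differ")
        if not np.all(np.isfinite(self.vector)):
            raise ValueError("force vector must be finite")


@dataclass(frozen=True)
class JointLoad:
    """Reaction force at a joint with its additive decomposition."""

    joint: str  # "J1" | "J2"
    force: np.ndarray  # total reaction (N)
    Rx: float  # track reaction at this instant (N)
    contributions: dict = field(default_factory=dict)  # name -> (2,) array

    def __post_init__(self) -> None:
        total = sum(self.contributions.values())
        if not np.allclose(total, self.force, atol=1e-9):
            raise ValueError("decomposition does not sum to the total reaction")


def _frames(state: ChainState):
    u1 = np.array([math.cos(state.theta1), math.sin(state.theta1)])
    w1 = np.array([-math.sin(state.theta1), math.cos(state.theta1)])
    u2 = np.array([math.cos(state.theta2), math.sin(state.theta2)])
    w2 = np.array([-math.sin(state.theta2), math.cos(state.theta2)])
    return u1, w1, u2, w2


def _application_point(f: MuscleForce, state: ChainState, chain: ChainParams) -> np.ndarray:
    """Global position of the muscle attachment on its loaded link."""
    u1, w1, u2, w2 = _frames(state)
    s, n = f.point
    if f.insertion_link == 1:
        return s * u1 + n * w1  # J1 at origin
    J2 = chain.l1 * u1
    return J2 + s * u2 + n * w2


def _cross_z(r: np.ndarray, F: np.ndarray) -> float:
    return float(r[0] * F[1] - r[1] * F[0])


def muscle_torques(
    forces: list[MuscleForce], state: ChainState, chain: ChainParams
) -> tuple[float, float]:
    """Joint torques (tau1, tau2) of a muscle force set, distal convention.

    tau2 is the moment about J2 of all forces acting on link 2; tau1 the
    moment about J1 of the forces that muscles spanning the shoulder exert
    on the links distal to it (single-joint shoulder muscles on link 1,
    two-joint muscles on link 2).
    """
    u1, _, _, _ = _frames(state)
    J1 = np.zeros(2)
    J2 = chain.l1 * u1
    tau1 = 0.0
    tau2 = 0.0
    for f in forces:
        P = _application_point(f, state, chain)
        F = np.asarray(f.vector, dtype=float)
        if f.insertion_link == 2:
            tau2 += _cross_z(P - J2, F)  # both F21 and F20 act on link 2
            if f.origin_link == 0:  # two-joint muscle also spans J1
                tau1 += _cross_z(P - J1, F)
        elif f.insertion_link == 1 and f.origin_link == 0:
            tau1 += _cross_z(P - J1, F)
        # F12 (elbow muscles pulling on link 1) contribute to neither torque
    return tau1, tau2


def track_reaction(
    state: ChainState, theta1_ddot: float, tau2: float, chain: ChainParams, d: float
) -> float:
    """Horizontal track reaction Rx (N) from the link-2 moment balance."""
    B, _, C = constraint_derivatives(state, chain)
    theta2_ddot = B * theta1_ddot + C * state.theta1_dot**2
    s2 = math.sin(state.theta2)
    Dang = state.theta2 - state.theta1
    cD, sD = math.cos(Dang), math.sin(Dang)
    num = (
        tau2
        - chain.m2 * chain.g * chain.lC2 * math.cos(state.theta2)
        - chain.I2 * theta2_ddot
        - chain.m2 * chain.lC2 * chain.l1 * (theta1_ddot * cD + state.theta1_dot**2 * sD)
    )
    return num / (chain.l2 * s2)


def _muscle_sums(forces: list[MuscleForce], link: int) -> np.ndarray:
    """Net muscle force on ``link`` (including reactions of muscles it anchors)."""
    total = np.zeros(2)
    for f in forces:
        F = np.asarray(f.vector, dtype=float)
        if f.insertion_link == link:
            total += F
        elif f.origin_link == link:
            total -= F  # action-reaction on the origin link
    return total


def elbow_reaction(
    state: ChainState,
    theta1_ddot: float,
    tau2: float,
    forces: list[MuscleForce] | None,
    chain: ChainParams,
    d: float,
) -> JointLoad:
    """Reaction phi21 exerted by the upper arm on link 2 (N).

    Newton balance of link 2: ``phi21 = m2*a_C2 - m2*g - sum(F21) -
    sum(F20) - Rx*x_hat``.
    """
    forces = forces or []
    _, a_C2 = point_accelerations(state, theta1_ddot, chain)
    Rx = track_reaction(state, theta1_ddot, tau2, chain, d)
    weight = np.array([0.0, -chain.m2 * chain.g])
    muscles = sum(
        (np.asarray(f.vector, dtype=float) for f in forces if f.insertion_link == 2),
        np.zeros(2),
    )
    contributions = {
        "inertial": chain.m2 * a_C2,
        "gravity": -weight,
        "muscle": -muscles,
        "track": -np.array([Rx, 0.0]),
    }
    total = sum(contributions.values())
    return JointLoad(joint="J2", force=total, Rx=Rx, contributions=contributions)


def shoulder_reaction(
    state: ChainState,
    theta1_ddot: float,
    tau2: float,
    forces: list[MuscleForce] | None,
    chain: ChainParams,
    d: float,
) -> JointLoad:
    """Reaction phi10 exerted by the trunk on the upper arm (N).

    System Newton balance: ``phi10 = m1*a_C1 + m2*a_C2 - (m1+m2)*g -
    sum(F10) - sum(F20) - Rx*x_hat`` (muscle forces internal to the
    two-link system cancel).
    """
    forces = forces or []
    a_C1 = com_acceleration_link1(state, theta1_ddot, chain)
    _, a_C2 = point_accelerations(state, theta1_ddot, chain)
    Rx = track_reaction(state, theta1_ddot, tau2, chain, d)
    weight = np.array([0.0, -(chain.m1 + chain.m2) * chain.g])
    muscles = sum(
        (
            np.asarray(f.vector, dtype=float)
            for f in forces
            if f.origin_link == 0 and f.insertion_link in (1, 2)
        ),
        np.zeros(2),
    )
    contributions = {
        "inertial": chain.m1 * a_C1 + chain.m2 * a_C2,
        "gravity": -weight,
        "muscle": -muscles,
        "track": -np.array([Rx, 0.0]),
    }
    total = sum(contributions.values())
    return JointLoad(joint="J1", force=total, Rx=Rx, contributions=contributions)


def check_torque_consistency(
    forces: list[MuscleForce],
    state: ChainState,
    chain: ChainParams,
    tau1: float,
    tau2: float,
    tol: float = 1e-6,
) -> bool:
    """Whether a force set realises the scenario torques to ``tol`` (N*m)."""
    t1, t2 = muscle_torques(forces, state, chain)
    return abs(t1 - tau1) <= tol and abs(t2 - tau2) <= tol
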
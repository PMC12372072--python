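"""Torque-driven forward dynamics of the single-DOF closed chain.

The equation of motion in the shoulder angle reads

    tau1 = tau2*(1+A) + m1*g*lC1*c1 + m2*g*l1*c1
           + (I1 + m2*l1^2)*th1dd
           + m2*l1*lC2*(th2dd*cosD - th2d^2*sinD)
           - A*(m2*g*lC2*c2 + I2*th2dd + m2*lC2*l1*(th1dd*cosD + th1d^2*sinD))

with ``A = l1 s1/(l2 s2)``, ``D = theta2 - theta1`` and the constraint
closure ``th2dd = B*th1dd + C*th1d^2`` (``B = -A``).  Collecting the
``th1dd`` terms gives an effective inertia ``M_eff(theta1) > 0`` and an
explicit ODE integrated with adaptive Runge-Kutta.

A lift starts at rest.  It *completes* at lockout (theta2 = theta1),
*fails* if the barbell velocity returns to zero after motion onset (the
chain would reverse), and *rests* if the torque cannot break equilibrium.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .kinematics import ChainState, lockout_angle, max_height, solve_theta2
from .model import ChainParams, ScenarioConfig
from .statics import path_max_tau1, tau1_eq_shared

_SAMPLE_HZ = 1000.0


class ModelValidityError(RuntimeError):
    """Effective inertia lost positivity: outside the model's valid range."""


def _coeffs(theta1: float, theta1_dot: float, chain: ChainParams, d: float):
    s1, c1 = math.sin(theta1), math.cos(theta1)
    c2 = (d - chain.l1 * c1) / chain.l2
    c2 = min(1.0, max(-1.0, c2))
    s2 = math.sqrt(max(1.0 - c2 * c2, 1e-16))
    l1, l2 = chain.l1, chain.l2
    A = l1 * s1 / (l2 * s2)
    B = -A
    C = -(l1 * c1) / (l2 * s2) - (l1 * s1) ** 2 * c2 / (l2**2 * s2**3)
    theta2 = math.atan2(s2, c2)
    return s1, c1, s2, c2, theta2, A, B, C


def angular_acceleration(
    state: ChainState, tau1: float, tau2: float, chain: ChainParams, d: float
) -> float:
    """Shoulder angular acceleration under raw joint torques (N*m)."""
    return _theta1_ddot(state.theta1, state.theta1_dot, tau1, tau2, chain, d)


def _theta1_ddot(
    theta1: float, theta1_dot: float, tau1: float, tau2: float, chain: ChainParams, d: float
) -> float:
    s1, c1, s2, c2, theta2, A, B, C = _coeffs(theta1, theta1_dot, chain, d)
    g = chain.g
    m1, m2 = chain.m1, chain.m2
    l1, lC1, lC2 = chain.l1, chain.lC1, chain.lC2
    I1, I2 = chain.I1, chain.I2
    D = theta2 - theta1
    cD, sD = math.cos(D), math.sin(D)
    w1sq = theta1_dot**2
    w2sq = (B * theta1_dot) ** 2
    M_eff = I1 + m2 * l1**2 + m2 * l1 * lC2 * B * cD - A * (I2 * B + m2 * lC2 * l1 * cD)
    if M_eff <= 0:
        raise ModelValidityError("effective inertia non-positive")
    Q = (
        tau1
        - tau2 * (1.0 + A)
        - m1 * g * lC1 * c1
        - m2 * g * l1 * c1
        - m2 * l1 * lC2 * (C * w1sq * cD - w2sq * sD)
        + A * (m2 * g * lC2 * c2 + I2 * C * w1sq + m2 * lC2 * l1 * w1sq * sD)
    )
    return Q / M_eff


@dataclass(frozen=True)
class Trajectory:
    """Sampled lift trajectory with outcome flag."""

    t: np.ndarray
    theta1: np.ndarray
    theta1_dot: np.ndarray
    yP: np.ndarray
    yP_dot: np.ndarray
    outcome: str  # "completed" | "failed" | "rest"
    scenario: ScenarioConfig

    def state(self, i: int, chain: ChainParams) -> ChainState:
        return ChainState.from_theta1(
            float(self.theta1[i]), float(self.theta1_dot[i]), chain, self.scenario.d, float(self.t[i])
        )


@dataclass(frozen=True)
class StickingFeatures:
    """First velocity peak and subsequent minimum of a lift."""

    yP_peak: float
    v_peak: float
    t_peak: float
    yP_min: float
    v_min: float
    t_min: float
    height_above_start: float


def _velocity_arrays(theta1, theta1_dot, chain: ChainParams, d: float):
    c1 = np.cos(theta1)
    s1 = np.sin(theta1)
    c2 = np.clip((d - chain.l1 * c1) / chain.l2, -1.0, 1.0)
    s2 = np.sqrt(np.maximum(1.0 - c2 * c2, 1e-16))
    B = -chain.l1 * s1 / (chain.l2 * s2)
    yP = chain.l1 * s1 + chain.l2 * s2
    yP_dot = (chain.l1 * c1 + chain.l2 * c2 * B) * theta1_dot
    return yP, yP_dot


def simulate_lift(
    chain: ChainParams,
    scenario: ScenarioConfig,
    t_max: float = 30.0,
    rtol: float = 1e-9,
    atol: float = 1e-12,
    onset_height: float = 1e-3,
) -> Trajectory:
    """Integrate a lift from rest under constant joint torques.

    Two integration phases: first until the bar has risen ``onset_height``
    (1 mm) above the start — if it never does within ``t_max`` the outcome
    is ``"rest"`` — then with termination events armed for lockout
    (``theta2 - theta1 = 0``, outcome ``"completed"``) and for the shoulder
    velocity crossing zero from above (outcome ``"failed"``).  Dense output
    is sampled at 1 kHz for feature detection.
    """
    scenario.validate(chain)
    tau1, tau2 = scenario.torques(chain)
    if tau1 < 0:
        raise ValueError("tau1 must be >= 0")
    d = scenario.d
    th0 = scenario.theta1_0
    y0, _ = _velocity_arrays(np.array([th0]), np.array([0.0]), chain, d)
    y_start = float(y0[0])

    def rhs(t, y):
        return [y[1], _theta1_ddot(y[0], y[1], tau1, tau2, chain, d)]

    def ev_onset(t, y):
        yP, _ = _velocity_arrays(np.array([y[0]]), np.array([y[1]]), chain, d)
        return float(yP[0]) - (y_start + onset_height)

    ev_onset.terminal = True
    ev_onset.direction = 1

    def ev_reverse(t, y):
        return y[1]

    ev_reverse.terminal = True
    ev_reverse.direction = -1

    sol1 = solve_ivp(
        rhs, (0.0, t_max), [th0, 0.0], events=[ev_onset, ev_reverse],
        rtol=rtol, atol=atol, dense_output=True, max_step=0.05,
    )
    pieces = [sol1]
    outcome = "rest"
    if sol1.t_events[0].size:  # motion onset reached: integrate the lift
        t1 = float(sol1.t_events[0][0])
        y1 = sol1.y_events[0][0]

        def ev_lockout(t, y):
            th2 = float(solve_theta2(y[0], chain, d))
            return th2 - y[0]

        ev_lockout.terminal = True
        ev_lockout.direction = -1

        sol2 = solve_ivp(
            rhs, (t1, t_max), y1, events=[ev_lockout, ev_reverse],
            rtol=rtol, atol=atol, dense_output=True, max_step=0.05,
        )
        pieces.append(sol2)
        if sol2.t_events[0].size:
            outcome = "completed"
        elif sol2.t_events[1].size:
            outcome = "failed"
        else:
            outcome = "failed"  # ran out of time mid-lift
    elif sol1.t_events[1].size:
        outcome = "rest"  # never left the 1 mm onset band

    t_end = float(pieces[-1].t[-1])
    n = max(int(t_end * _SAMPLE_HZ), 200)
    t = np.linspace(0.0, t_end, n)
    theta1 = np.empty(n)
    theta1_dot = np.empty(n)
    lo = 0.0
    for sol in pieces:
        hi = float(sol.t[-1])
        mask = (t >= lo) & (t <= hi + 1e-15)
        if mask.any():
            vals = sol.sol(np.clip(t[mask], sol.t[0], sol.t[-1]))
            theta1[mask] = vals[0]
            theta1_dot[mask] = vals[1]
        lo = hi
    yP, yP_dot = _velocity_arrays(theta1, theta1_dot, chain, d)
    return Trajectory(t=t, theta1=theta1, theta1_dot=theta1_dot, yP=yP, yP_dot=yP_dot,
                      outcome=outcome, scenario=scenario)


def sticking_features(traj: Trajectory) -> StickingFeatures | None:
    """First interior velocity peak and the subsequent minimum, if any.

    Returns ``None`` for a monotone velocity profile.  Note that every
    completed lift decelerates to zero exactly at lockout (dyP/dtheta1
    vanishes there), so a terminal peak with no recovered minimum after it
    does not count as a sticking pattern.
    """
    v = traj.yP_dot
    sign = np.sign(np.diff(v))
    maxima = np.nonzero((sign[:-1] > 0) & (sign[1:] < 0))[0] + 1
    minima = np.nonzero((sign[:-1] < 0) & (sign[1:] > 0))[0] + 1
    for i in maxima:
        later = minima[minima > i]
        if later.size:
            j = int(later[0])
            return StickingFeatures(
                yP_peak=float(traj.yP[i]), v_peak=float(v[i]), t_peak=float(traj.t[i]),
                yP_min=float(traj.yP[j]), v_min=float(v[j]), t_min=float(traj.t[j]),
                height_above_start=float(traj.yP[j] - traj.yP[0]),
            )
    return None


def has_sticking_pattern(traj: Trajectory) -> bool:
    """Velocity dip (peak-then-recovered-minimum) or outright failure."""
    return traj.outcome == "failed" or sticking_features(traj) is not None


def critical_tau1(
    chain: ChainParams,
    scenario_template: ScenarioConfig,
    criterion: str = "quasistatic",
    bracket: tuple[float, float] | None = None,
    tol: float = 1e-5,
    t_max: float = 30.0,
) -> float:
    """Critical normalised shoulder torque tau1*/Mg for a scenario.

    criterion
        ``"quasistatic"``
            Maximum of the shared equilibrium torque along the lift path.
            A constant torque below it cannot balance gravity everywhere
            on the path, so velocity extrema (the sticking pattern) must
            emerge; above it the drive exceeds equilibrium at every height.
        ``"extrema"``
            Dynamic bisection: largest tau1/Mg whose simulated trajectory
            still shows a velocity dip (or fails).  Inertia lets a moving
            bar coast through the equilibrium hump, so this threshold can
            sit below the quasi-static one, markedly so for narrow grips.
        ``"completion"``
            Smallest tau1/Mg whose lift completes — the maximal-lift
            torque, at which the sticking-region velocity minimum grazes
            zero.
    """
    sc = scenario_template
    if criterion == "quasistatic":
        tau_max, _ = path_max_tau1(chain, sc.d, sc.k, sc.theta1_0)
        return tau_max

    if criterion == "extrema":
        def predicate(tau):
            traj = simulate_lift(chain, _with_tau(sc, tau), t_max=t_max)
            # below threshold: a dip, a failed lift, or no lift-off at all
            return traj.outcome != "completed" or sticking_features(traj) is not None
    elif criterion == "completion":
        def predicate(tau):
            traj = simulate_lift(chain, _with_tau(sc, tau), t_max=t_max)
            return traj.outcome != "completed"
    else:
        raise ValueError(f"unknown criterion {criterion!r}")

    if bracket is None:
        # start just above the equilibrium torque at the initial angle
        tau0 = float(tau1_eq_shared(sc.theta1_0, sc.k, chain, sc.d, normalize=True))
        bracket = (max(tau0, 1e-3) + 1e-4, 2.0)
    lo, hi = bracket
    if not predicate(lo):
        raise ValueError("criterion already unsatisfied at the lower bracket")
    if predicate(hi):
        raise ValueError("criterion still satisfied at the upper bracket")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if predicate(mid):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _with_tau(sc: ScenarioConfig, tau1: float) -> ScenarioConfig:
    from dataclasses import replace

    return replace(sc, tau1=float(tau1))


def maximal_lift_features(
    chain: ChainParams,
    scenario_template: ScenarioConfig,
    eps: float = 2e-5,
    tol: float = 1e-5,
) -> tuple[float, StickingFeatures]:
    """Sticking features of the maximal lift (completion-limit torque + eps).

    Returns ``(tau1_limit/Mg, features)`` where the features are measured
    on the just-completing trajectory.
    """
    tau_lim = critical_tau1(chain, scenario_template, criterion="completion", tol=tol)
    traj = simulate_lift(chain, _with_tau(scenario_template, tau_lim + eps))
    if traj.outcome != "completed":
        traj = simulate_lift(chain, _with_tau(scenario_template, tau_lim + 10 * eps))
    feats = sticking_features(traj)
    if feats is None:
        raise RuntimeError("maximal lift shows no sticking pattern")
    return tau_lim, feats
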
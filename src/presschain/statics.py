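"""Static equilibrium analysis: torque curves and the critical grip distance.

With the chain at rest, the shoulder torque needed to hold the barbell at a
given height is

    tau1_eq = m1*g*lC1*cos(th1) + m2*g*l1*cos(th1)
              - m2*g*lC2 * (l1 sin th1)/(l2 sin th2) * cos(th2)

and under the torque-sharing program tau2 = -k*tau1 the shared equilibrium
torque is ``tau1_eq / (1 + k*(1 + A))`` with ``A = l1 sin th1/(l2 sin th2)``.

For narrow grips the equilibrium curve tau1_eq(yP) develops an interior
local maximum — the geometric precondition for a sticking region.  The
largest grip offset at which this occurs is the critical distance d*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .kinematics import (
    endpoint_height,
    feasible_theta1_range,
    lockout_angle,
    max_height,
    solve_theta2,
    theta1_of_height,
)
from .model import ChainParams


def _A(theta1, chain: ChainParams, d: float):
    theta2 = solve_theta2(theta1, chain, d)
    s2 = np.sin(theta2)
    if np.any(np.abs(s2) < 1e-12):
        raise ZeroDivisionError("singular configuration: sin(theta2) = 0")
    return chain.l1 * np.sin(theta1) / (chain.l2 * s2), theta2


def tau1_eq(theta1, chain: ChainParams, d: float, normalize: bool = False):
    """Equilibrium shoulder torque with zero elbow torque (N*m).

    With ``normalize=True`` the torque is divided by M*g.  Vectorised over
    ``theta1``.
    """
    A, theta2 = _A(theta1, chain, d)
    g = chain.g
    tau = (
        chain.m1 * g * chain.lC1 * np.cos(theta1)
        + chain.m2 * g * chain.l1 * np.cos(theta1)
        - chain.m2 * g * chain.lC2 * A * np.cos(theta2)
    )
    return tau / (chain.M * chain.g) if normalize else tau


def tau2_eq(theta1, chain: ChainParams, d: float, normalize: bool = False):
    """Equilibrium elbow torque with zero shoulder torque (N*m, extensor < 0).

    ``-tau2_eq = tau1_eq / (1 + A)``; raises on the singular denominator.
    """
    A, _ = _A(theta1, chain, d)
    denom = 1.0 + A
    if np.any(np.abs(denom) < 1e-12):
        raise ZeroDivisionError("singular configuration: 1 + A = 0")
    tau = -tau1_eq(theta1, chain, d) / denom
    return tau / (chain.M * chain.g) if normalize else tau


def tau1_eq_shared(theta1, k: float, chain: ChainParams, d: float, normalize: bool = False):
    """Equilibrium shoulder torque under the sharing program tau2 = -k*tau1."""
    A, _ = _A(theta1, chain, d)
    denom = 1.0 + k * (1.0 + A)
    if np.any(np.abs(denom) < 1e-12):
        raise ZeroDivisionError("singular denominator 1 + k(1+A) = 0")
    tau = tau1_eq(theta1, chain, d) / denom
    return tau / (chain.M * chain.g) if normalize else tau


@dataclass(frozen=True)
class EquilibriumCurve:
    """tau1_eq/(Mg) sampled against barbell height for one (d, k) scenario."""

    yP: np.ndarray
    tau_over_Mg: np.ndarray
    d: float
    k: float
    local_max: tuple[float, float] | None  # (yP*, tau*/Mg) or None


def _grid_theta_range(chain: ChainParams, d: float, y_start: float | None) -> tuple[float, float]:
    lo, hi = feasible_theta1_range(chain, d)
    lo += 1e-6
    y_lo = float(endpoint_height(lo, chain, d))
    if y_start is None:
        # default: from the height where the bar crosses yP = 0 (shoulder
        # level) or the feasible minimum, whichever is higher
        y_start = max(0.0, y_lo + 1e-9)
    th_lo = theta1_of_height(max(y_start, y_lo + 1e-9), chain, d)
    return th_lo, hi - 1e-9


def equilibrium_curve(
    chain: ChainParams,
    d: float,
    k: float = 0.0,
    n_grid: int = 2000,
    y_start: float | None = None,
) -> EquilibriumCurve:
    """Equilibrium torque curve on a uniform yP grid with extremum detection.

    The grid spans from ``y_start`` (default: shoulder height yP = 0, or the
    feasible minimum if higher) up to the lockout height.  An *interior*
    local maximum — a discrete rise-then-fall of the curve away from both
    endpoints — is refined by bounded scalar maximisation to ~1e-6 m.
    """
    if n_grid < 100:
        raise ValueError("n_grid must be >= 100")
    th_lo, th_hi = _grid_theta_range(chain, d, y_start)
    y_lo = float(endpoint_height(th_lo, chain, d))
    y_hi = max_height(chain, d)
    yP = np.linspace(y_lo, y_hi - 1e-9, n_grid)
    # invert the monotone yP(theta) map on a dense grid (the curve itself is
    # evaluated exactly at the interpolated angles)
    th_dense = np.linspace(th_lo, th_hi, 4 * n_grid)
    y_dense = endpoint_height(th_dense, chain, d)
    theta = np.interp(yP, y_dense, th_dense)
    tau = tau1_eq_shared(theta, k, chain, d, normalize=True)

    local_max = None
    sign = np.sign(np.diff(tau))
    rise_fall = np.nonzero((sign[:-1] > 0) & (sign[1:] < 0))[0]
    if rise_fall.size:
        i = int(rise_fall[0]) + 1  # grid index of the discrete maximum
        lo_y, hi_y = yP[max(i - 1, 0)], yP[min(i + 1, n_grid - 1)]
        res = minimize_scalar(
            lambda y: -float(tau1_eq_shared(theta1_of_height(y, chain, d), k, chain, d, normalize=True)),
            bounds=(lo_y, hi_y),
            method="bounded",
            options={"xatol": 1e-6},
        )
        local_max = (float(res.x), float(-res.fun))
    return EquilibriumCurve(yP=yP, tau_over_Mg=tau, d=d, k=k, local_max=local_max)


def has_interior_maximum(
    chain: ChainParams, d: float, k: float = 0.0, n_grid: int = 2000, y_start: float | None = None
) -> bool:
    """Whether tau1_eq_shared(yP) has an interior local maximum for this d."""
    return equilibrium_curve(chain, d, k, n_grid=n_grid, y_start=y_start).local_max is not None


def critical_d(
    chain: ChainParams,
    k: float = 0.0,
    tol: float = 1e-3,
    d_bracket: tuple[float, float] | None = None,
    n_grid: int = 2000,
) -> float:
    """Critical grip offset d*: largest d with an interior equilibrium maximum.

    Bisection on ``d`` to ``tol`` (default 1 mm).  Below d* the curve has a
    relative maximum (a sticking region can exist); above it the curve
    descends monotonically.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    lo, hi = d_bracket if d_bracket else (0.02, 0.9 * chain.reach)
    if not has_interior_maximum(chain, lo, k, n_grid):
        raise ValueError(f"no interior maximum even at d = {lo}")
    if has_interior_maximum(chain, hi, k, n_grid):
        raise ValueError(f"interior maximum persists at d = {hi}")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if has_interior_maximum(chain, mid, k, n_grid):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def path_max_tau1(
    chain: ChainParams,
    d: float,
    k: float,
    theta1_0: float,
    n_grid: int = 4000,
) -> tuple[float, float]:
    """Maximum normalised equilibrium torque along a lift path.

    Scans tau1_eq_shared/(Mg) from the start angle to lockout and refines
    the maximum; returns ``(tau_max/Mg, yP_at_max)``.  This is the
    quasi-static critical torque: a constant shoulder torque below it
    cannot hold equilibrium everywhere on the path, so a deceleration
    (sticking) region must appear somewhere before lockout.
    """
    th_hi = lockout_angle(chain, d)
    theta = np.linspace(theta1_0, th_hi - 1e-9, n_grid)
    tau = tau1_eq_shared(theta, k, chain, d, normalize=True)
    i = int(np.argmax(tau))
    lo = theta[max(i - 1, 0)]
    hi = theta[min(i + 1, n_grid - 1)]
    res = minimize_scalar(
        lambda th: -float(tau1_eq_shared(th, k, chain, d, normalize=True)),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    th_star = float(res.x)
    return float(-res.fun), float(endpoint_height(th_star, chain, d))
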
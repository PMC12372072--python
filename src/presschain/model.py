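"""Chain parameters, anthropometric calibration and scenario presets.

The mechanical system is a planar two-link chain: link 1 is the upper arm
(shoulder joint J1 fixed at the origin), link 2 the combined forearm+hand
segment carrying a concentrated mass ``M`` (half the loaded barbell) at its
distal end P.  P slides on a frictionless vertical track a horizontal
distance ``d`` from J1, which closes the chain and leaves one degree of
freedom (the shoulder angle ``theta1``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq, least_squares

G_STANDARD = 9.81  # m/s^2

# Adult anthropometric table (fractions of body mass / segment length,
# radius of gyration about the proximal joint), Winter-style values for the
# upper arm and the combined forearm+hand segment.
UPPER_ARM_MASS_FRACTION = 0.028
UPPER_ARM_COM_FRACTION = 0.436
UPPER_ARM_ROG_PROXIMAL = 0.542
FOREARM_HAND_MASS_FRACTION = 0.022
FOREARM_HAND_COM_FRACTION = 0.682
FOREARM_HAND_ROG_PROXIMAL = 0.827

#: Default body mass (kg) of the simulated lifter, an intermediate-level
#: adult; segment masses are small against the barbell mass, so results are
#: insensitive to this choice.
DEFAULT_BODY_MASS = 75.0


class CalibrationError(RuntimeError):
    """Raised when segment lengths cannot be recovered from printed heights."""


@dataclass(frozen=True)
class ChainParams:
    """Geometric and inertial description of the two-link chain.

    Parameters
    ----------
    l1, l2 : float
        Link lengths (m): upper arm and forearm+hand.
    lC1, lC2 : float
        Distances (m) from J1 to the centre of mass of link 1 and from J2 to
        the centre of mass of the *combined* link 2 (forearm+hand plus the
        concentrated mass ``M`` at the endpoint).
    m1, m2 : float
        Link masses (kg); ``m2`` includes ``M``.
    I1, I2 : float
        Moments of inertia (kg m^2) about the proximal joints J1 and J2;
        ``I2`` includes the ``M l2^2`` contribution of the endpoint mass.
    M : float
        Concentrated endpoint mass (kg), half of the loaded barbell.
    g : float
        Gravitational acceleration (m/s^2).
    """

    l1: float
    l2: float
    lC1: float
    lC2: float
    m1: float
    m2: float
    I1: float
    I2: float
    M: float
    g: float = G_STANDARD

    def __post_init__(self) -> None:
        for name in ("l1", "l2", "lC1", "lC2", "m1", "m2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.lC1 > self.l1 + 1e-12:
            raise ValueError("lC1 must not exceed l1")
        if self.lC2 > self.l2 + 1e-12:
            raise ValueError("lC2 must not exceed l2")
        if self.M < 0:
            raise ValueError("M must be non-negative")
        if self.m2 <= self.M:
            raise ValueError("m2 must include (exceed) the concentrated mass M")
        if self.I1 < self.m1 * self.lC1**2 - 1e-12:
            raise ValueError("I1 must satisfy I1 >= m1*lC1^2")
        if self.I2 < self.m2 * self.lC2**2 - 1e-12:
            raise ValueError("I2 must satisfy I2 >= m2*lC2^2")

    @property
    def reach(self) -> float:
        """Maximum horizontal reach l1 + l2 (m)."""
        return self.l1 + self.l2

    def with_mass(self, M: float, body_mass: float = DEFAULT_BODY_MASS) -> "ChainParams":
        """Return a copy rebuilt for a different concentrated mass ``M``."""
        return build_chain(self.l1, self.l2, body_mass=body_mass, M=M, g=self.g)


@dataclass(frozen=True)
class ScenarioConfig:
    """Simulation scenario: geometry, load and torque program.

    ``tau1`` is the shoulder torque normalised to M*g (dimensionless);
    the elbow torque is entered through the sharing ratio ``k`` with
    tau2 = -k*tau1 (positive ``k`` means an elbow *extensor* torque).
    """

    d: float
    theta1_0: float
    M: float
    tau1: float = 0.0
    k: float = 0.0
    exercise: str = "custom"
    tau2_raw: float | None = None  # explicit tau2 in N*m, overrides k

    def validate(self, chain: ChainParams) -> None:
        if not (0.0 < self.d < chain.reach):
            raise ValueError("d must lie strictly between 0 and l1+l2")
        if abs(self.d - chain.l1 * math.cos(self.theta1_0)) > chain.l2 + 1e-12:
            raise ValueError("initial shoulder angle infeasible for the barbell constraint")
        if self.k < 0:
            raise ValueError("torque-sharing ratio k must be >= 0")

    def torques(self, chain: ChainParams) -> tuple[float, float]:
        """Raw joint torques (N*m): (tau1, tau2)."""
        t1 = self.tau1 * self.M * chain.g
        t2 = self.tau2_raw if self.tau2_raw is not None else -self.k * t1
        return t1, t2


# Printed study geometry: (d, theta1_0, start height, lockout height), SI.
BENCH_GEOMETRY = (0.25, math.radians(-45.0), 0.09, 0.59)
OVERHEAD_GEOMETRY = (0.10, math.radians(-60.0), 0.04, 0.63)
BENCH_MASS = 50.0  # kg, half of a 100 kg bench-press barbell
OVERHEAD_MASS = 33.3  # kg, half of a 66.6 kg overhead-press barbell


def _height(theta1: float, l1: float, l2: float, d: float) -> float:
    c2 = (d - l1 * np.cos(theta1)) / l2
    s2sq = 1.0 - c2 * c2
    if np.any(np.asarray(s2sq) < 0):
        return np.nan
    return l1 * np.sin(theta1) + l2 * np.sqrt(s2sq)


def calibrate_segment_lengths(
    bench_start: tuple[float, float, float],
    overhead_start: tuple[float, float, float],
    bracket: tuple[float, float] = (0.1, 0.6),
) -> tuple[float, float]:
    """Recover (l1, l2) from two exercise start configurations.

    Each configuration is ``(d, theta1_0, yP_start)``; the two nonlinear
    equations ``yP(theta1_0; l1, l2, d) = yP_start`` are solved exactly by
    2-D root finding.  Raises :class:`CalibrationError` when the system is
    rank-deficient (identical configurations) or has no root in ``bracket``.
    """
    (d_b, th_b, y_b), (d_o, th_o, y_o) = bench_start, overhead_start
    if np.allclose(bench_start, overhead_start):
        raise CalibrationError("identical start configurations are underdetermined")

    def residual(x):
        l1, l2 = x
        r1 = _height(th_b, l1, l2, d_b) - y_b
        r2 = _height(th_o, l1, l2, d_o) - y_o
        return [1.0 if np.isnan(r1) else r1, 1.0 if np.isnan(r2) else r2]

    lo, hi = bracket
    best = None
    for x0 in ((0.3, 0.3), (0.25, 0.35), (0.35, 0.25), (0.2, 0.4), (0.45, 0.45)):
        sol = least_squares(residual, x0, bounds=([lo, lo], [hi, hi]), xtol=1e-15, ftol=1e-15, gtol=1e-15)
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or np.max(np.abs(residual(best.x))) > 1e-9:
        raise CalibrationError("no (l1, l2) root in the physiological bracket")
    return float(best.x[0]), float(best.x[1])


def calibrate_from_printed_heights(
    bench: tuple[float, float, float, float] = BENCH_GEOMETRY,
    overhead: tuple[float, float, float, float] = OVERHEAD_GEOMETRY,
) -> tuple[float, float]:
    """Least-squares calibration of (l1, l2) to the full printed yP ranges.

    Uses all four printed heights — both start heights and both lockout
    heights ``sqrt((l1+l2)^2 - d^2)`` — which are individually rounded to
    the centimetre; the overdetermined fit recovers the geometry that is
    consistent with all of them (l1 ~ l2 ~ 0.32 m).
    """
    (d_b, th_b, y_b, ymax_b) = bench
    (d_o, th_o, y_o, ymax_o) = overhead

    def residual(x):
        l1, l2 = x
        r = [
            _height(th_b, l1, l2, d_b) - y_b,
            math.sqrt(max((l1 + l2) ** 2 - d_b**2, 0.0)) - ymax_b,
            _height(th_o, l1, l2, d_o) - y_o,
            math.sqrt(max((l1 + l2) ** 2 - d_o**2, 0.0)) - ymax_o,
        ]
        return [1.0 if np.isnan(v) else v for v in r]

    sol = least_squares(residual, (0.3, 0.3), bounds=([0.1, 0.1], [0.6, 0.6]))
    if np.max(np.abs(residual(sol.x))) > 0.02:
        raise CalibrationError("printed heights inconsistent beyond 2 cm")
    return float(sol.x[0]), float(sol.x[1])


def build_chain(
    l1: float,
    l2: float,
    body_mass: float = DEFAULT_BODY_MASS,
    M: float = 0.0,
    g: float = G_STANDARD,
) -> ChainParams:
    """Assemble :class:`ChainParams` from segment lengths and a barbell load.

    Segment masses, centre-of-mass positions and moments of inertia come
    from the standard adult table scaled by ``body_mass``; the concentrated
    mass ``M`` is folded into link 2::

        m2  = m_fa + M
        lC2 = (m_fa*lC_fa + M*l2) / m2
        I2  = I_fa(about J2) + M*l2^2
    """
    if min(l1, l2, body_mass) <= 0:
        raise ValueError("lengths and body mass must be positive")
    if M < 0:
        raise ValueError("M must be non-negative")
    m1 = UPPER_ARM_MASS_FRACTION * body_mass
    lC1 = UPPER_ARM_COM_FRACTION * l1
    I1 = m1 * (UPPER_ARM_ROG_PROXIMAL * l1) ** 2
    m_fa = FOREARM_HAND_MASS_FRACTION * body_mass
    lC_fa = FOREARM_HAND_COM_FRACTION * l2
    I_fa = m_fa * (FOREARM_HAND_ROG_PROXIMAL * l2) ** 2
    m2 = m_fa + M
    lC2 = (m_fa * lC_fa + M * l2) / m2
    I2 = I_fa + M * l2**2
    return ChainParams(l1=l1, l2=l2, lC1=lC1, lC2=lC2, m1=m1, m2=m2, I1=I1, I2=I2, M=M, g=g)


def default_chain(M: float, body_mass: float = DEFAULT_BODY_MASS) -> ChainParams:
    """Chain with segment lengths calibrated to the printed study geometry."""
    l1, l2 = calibrate_from_printed_heights()
    return build_chain(l1, l2, body_mass=body_mass, M=M)


def bench_press(tau1: float = 0.0, k: float = 0.0, M: float = BENCH_MASS) -> ScenarioConfig:
    """Bench-press preset: d = 25 cm, theta1(0) = -45 deg, M = 50 kg."""
    d, th0, _, _ = BENCH_GEOMETRY
    return ScenarioConfig(d=d, theta1_0=th0, M=M, tau1=tau1, k=k, exercise="bench")


def overhead_press(tau1: float = 0.0, k: float = 0.0, M: float = OVERHEAD_MASS) -> ScenarioConfig:
    """Overhead-press preset: d = 10 cm, theta1(0) = -60 deg, M = 33.3 kg."""
    d, th0, _, _ = OVERHEAD_GEOMETRY
    return ScenarioConfig(d=d, theta1_0=th0, M=M, tau1=tau1, k=k, exercise="overhead")


SCENARIOS = {"bench": bench_press, "overhead": overhead_press}


def scenario_chain(scenario: ScenarioConfig, body_mass: float = DEFAULT_BODY_MASS) -> ChainParams:
    """Default calibrated chain matched to a scenario's barbell mass."""
    return default_chain(scenario.M, body_mass=body_mass)
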
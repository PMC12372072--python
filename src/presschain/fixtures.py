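"""Synthetic pseudo-experimental velocity traces for pipeline testing.

Real 1RM barbell traces show a rise, a sticking dip, a post-sticking rise
and a gradual terminal deceleration, overlaid with smooth measurement
noise.  The generator starts from a simulated maximal lift, blends in a
linear terminal deceleration to zero over a stated fraction of the lift,
and adds moving-average-smoothed Gaussian noise — deterministically for a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .dynamics import critical_tau1, simulate_lift
from .model import ChainParams, ScenarioConfig
from .similarity import VelocityTrace


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic pseudo-experimental 1RM velocity trace.

    ``tau1=None`` simulates a maximal lift (completion-limit torque found
    by bisection, plus a small margin).  ``decel_fraction`` is the final
    fraction of the lift over which velocity is tapered linearly to zero;
    ``noise_amplitude`` (m/s) and ``noise_window`` (samples of the
    smoothing moving average) shape the measurement noise.
    """

    scenario: ScenarioConfig
    tau1: float | None = None
    decel_fraction: float = 0.15
    noise_amplitude: float = 0.02
    noise_window: int = 25
    n_samples: int = 201
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.decel_fraction < 0.3:
            raise ValueError("decel_fraction must lie in [0, 0.3)")
        if self.noise_amplitude < 0:
            raise ValueError("noise_amplitude must be >= 0")


def model_velocity_trace(
    chain: ChainParams, scenario: ScenarioConfig, n_samples: int = 201, label: str = "model"
) -> VelocityTrace:
    """Simulated barbell velocity resampled to ``n_samples`` uniform times."""
    traj = simulate_lift(chain, scenario)
    if traj.outcome != "completed":
        raise RuntimeError(f"underlying lift did not complete (outcome={traj.outcome})")
    t = np.linspace(traj.t[0], traj.t[-1], n_samples)
    v = np.interp(t, traj.t, traj.yP_dot)
    return VelocityTrace(values=v, axis=t, label=label)


def synth_experimental_trace(spec: FixtureSpec, chain: ChainParams) -> VelocityTrace:
    """Generate a pseudo-experimental trace per ``spec``; deterministic per seed."""
    scenario = spec.scenario
    if spec.tau1 is None:
        tau_lim = critical_tau1(chain, scenario, criterion="completion")
        scenario = replace(scenario, tau1=tau_lim + 2e-4)
    else:
        scenario = replace(scenario, tau1=spec.tau1)
    trace = model_velocity_trace(chain, scenario, spec.n_samples, label=f"synthetic-{spec.seed}")
    v = trace.values.copy()
    n = v.size
    if spec.decel_fraction > 0:
        i0 = int(np.floor((1.0 - spec.decel_fraction) * (n - 1)))
        taper = np.linspace(1.0, 0.0, n - i0)
        v[i0:] = v[i0] * taper  # linear terminal deceleration to zero
    if spec.noise_amplitude > 0:
        rng = np.random.default_rng(spec.seed)
        noise = rng.normal(0.0, spec.noise_amplitude, n)
        win = max(1, min(spec.noise_window, n // 2))
        if win > 1:
            kernel = np.ones(win) / win
            pad = win // 2
            padded = np.concatenate([noise[:pad][::-1], noise, noise[-pad:][::-1]])
            noise = np.convolve(padded, kernel, mode="valid")[:n]
        v = v + noise
    return VelocityTrace(values=v, axis=trace.axis, label=trace.label)
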
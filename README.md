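# presschain

A closed-chain two-link simulator of barbell pressing — the bench press and
the overhead press — for strength-training biomechanics: static equilibrium
torque curves, torque-driven forward dynamics of the sticking region, joint
reaction forces, and constrained-DTW validation of simulated barbell
velocity waveforms against experimental traces.

## The model

The upper limb and half the barbell are a planar two-link chain. Link 1
(upper arm, length l₁) pivots at the shoulder J₁; link 2 (forearm+hand,
length l₂) carries a concentrated mass M — half the loaded barbell — at its
endpoint P, which slides on a frictionless **vertical track** at horizontal
offset *d* from the shoulder (grip width ≈ 2d + biacromial distance). The
track closes the kinematic chain:

    l₁ cos θ₁ + l₂ cos θ₂ = d,        y_P = l₁ sin θ₁ + l₂ sin θ₂,

leaving one degree of freedom, the shoulder angle θ₁. Muscles enter as a
shoulder torque τ₁ (transverse flexion for the bench, abduction for the
overhead press) and an elbow torque τ₂, usually coupled by a sharing ratio
k with τ₂ = −k·τ₁ (extensor). With A = l₁ sin θ₁ / (l₂ sin θ₂), holding
the bar still requires

    τ₁,eq = m₁ g l_C1 cos θ₁ + m₂ g l₁ cos θ₁ − m₂ g l_C2 A cos θ₂,

divided by 1 + k(1 + A) when the elbow shares the load. For narrow grips
this equilibrium curve τ₁,eq(y_P) has an interior local maximum — the
mechanical origin of the **sticking region**: a constant drive below that
maximum must decelerate somewhere mid-lift, producing the familiar velocity
dip, and the lift fails if the velocity reaches zero there. The largest
offset at which the maximum exists is the critical grip distance d*.
Forward dynamics integrates the single-DOF equation of motion under
constant torques from rest to lockout (θ₂ = θ₁) and extracts the velocity
peak/minimum; waveform validation segments velocity traces at those
landmarks and scores each region with a Sakoe–Chiba-banded DTW similarity
index SI = 1 − D/(D + L) plus a permutation test.

Segment lengths are calibrated (least squares) to the printed study
geometry — bench: d = 25 cm, θ₁(0) = −45°, bar from 9 cm to 59 cm;
overhead: d = 10 cm, θ₁(0) = −60°, 4 cm to 63 cm — giving
l₁ ≈ l₂ ≈ 0.32 m; masses and inertias come from standard adult
anthropometric tables with M folded into link 2.

## Worked example

Critical grip distance when the elbow extensor supplies half the shoulder
torque, and the quasi-static sticking threshold for the bench press:

```console
$ presschain critical-d --k 0.5
26.9
$ presschain critical-tau --exercise bench --k 0
0.34244
```

So with τ₂ = −τ₁/2 a sticking region can only exist for grip offsets below
≈ 27 cm, and with no elbow torque a bench press at d = 25 cm needs
τ₁ > 0.342·Mg for a monotone bar velocity. Simulating just above the
failure threshold shows the sticking dip:

```console
$ presschain simulate --exercise bench --tau1 0.3112 --k 0 --out traj.csv
[presschain] outcome=completed v_peak=0.564 m/s @ yP=0.239 m, v_min=0.197 m/s @ yP=0.469 m
```

The bar accelerates to 0.56 m/s at 24 cm, then decelerates through the
sticking region to a minimum of 0.20 m/s at 47 cm before re-accelerating
to lockout (59 cm). `traj.csv` holds the full time series (t_s,
theta1_rad, theta1_dot_rad_s, yP_m, yP_dot_m_s). Other subcommands:
`statics` (equilibrium curves), `loads` (track and joint reaction forces
along a trajectory), `synth` (seeded pseudo-experimental 1RM traces) and
`similarity` (region-wise cDTW with permutation p-values).

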
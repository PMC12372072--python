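# Methods

## Mechanical model

The upper limb and half the barbell form a planar closed chain: link 1
(upper arm) rotates about the fixed shoulder J1; link 2 (forearm+hand)
attaches at the elbow J2 and carries a concentrated mass M (half the
loaded barbell) at its endpoint P, which is constrained to a frictionless
vertical track a horizontal distance d from the shoulder. The constraint
`l1 cos th1 + l2 cos th2 = d` reduces the system to one degree of freedom,
the shoulder angle th1 (counter-clockwise from horizontal; the elbow-link
angle th2 takes the non-negative-sine branch, i.e. the bar stays above the
elbow's horizontal, which both exercises satisfy). The bench press —
physically supine — is represented in the same abstract frame, gravity
along −y. Muscles act as ideal torque generators: a shoulder torque tau1
(moments of shoulder-spanning muscle forces on the links distal to J1) and
an elbow torque tau2 (moments about J2 of forces on link 2); scenarios
couple them as tau2 = −k·tau1 with an extensor sharing ratio k ≥ 0.
Torques are constant over a lift — deliberately, to isolate the geometric
mechanism of the sticking region from activation dynamics and
force–length/velocity effects, which are out of scope.

Assumptions: rigid links, ideal revolute joints, planar motion, no track
friction, no scapulothoracic motion, elbow hyperextension disallowed
(integration terminates at lockout th2 = th1), lifts start at rest.

## Geometry and inertial parameters

Segment lengths are calibrated by least squares to the four printed
heights of the study conditions — bench (d = 25 cm, th1(0) = −45°) bar
path 9→59 cm, overhead (d = 10 cm, th1(0) = −60°) path 4→63 cm — because
the four numbers are individually rounded to the centimetre and jointly
overdetermine (l1, l2). The fit gives l1 = 0.3195 m, l2 = 0.3198 m with
residuals under 3 mm, and reproduces the lockout heights
`sqrt((l1+l2)² − d²)` as 58.8 and 63.1 cm. An exact two-point calibration
on the start heights alone is also provided
(`calibrate_segment_lengths`, residual < 1e−9 m) but is *not* the default:
start heights alone are consistent with a shorter arm (l1+l2 = 0.607 m)
that contradicts the printed lockouts.

Masses and inertias use standard adult anthropometric fractions (Winter):
upper arm mass 0.028·BM, COM at 0.436·l1, radius of gyration about the
proximal joint 0.542·l1; forearm+hand mass 0.022·BM, COM 0.682·l2, radius
of gyration 0.827·l2; default body mass BM = 75 kg, g = 9.81 m/s². The
concentrated mass is folded into link 2: m2 = m_fa + M,
lC2 = (m_fa·lC_fa + M·l2)/m2, I2 = I_fa + M·l2² (about J2). Because
M (50 kg bench / 33.3 kg overhead per chain) dwarfs the ~1.7 kg forearm,
every normalised result is insensitive to the table values at the level
of the reported precision.

## Statics and the critical grip distance

The equilibrium shoulder torque (elbow torque zero) is

    tau1_eq = m1 g lC1 cos th1 + m2 g l1 cos th1 − m2 g lC2 A cos th2,
    A = l1 sin th1 / (l2 sin th2),

and under sharing tau2 = −k·tau1 it divides by 1 + k(1+A). An independent
virtual-work oracle (numerical gradient of the constrained gravitational
potential) confirms the formula to 1e−8 relative in the tests. Curves are
reported normalised to M·g and plotted against bar height yP; the grid
runs from shoulder height (yP = 0, or the feasible minimum if higher) to
lockout. The elbow-only equilibrium torque is singular exactly at yP = 0,
where 1 + A = 0 (the elbow loses leverage on the bar); the shoulder curve
is regular there.

An *interior* local maximum of the curve — detected as a rise-then-fall of
first differences on a 2000-point grid, refined by bounded scalar
maximisation to 1e−6 m, endpoints excluded — is the geometric precondition
for a sticking region. `critical_d` bisects on d (tolerance 1 mm) for the
largest offset retaining such a maximum: 37.4 cm at k = 0, 26.9 cm at
k = 1/2, 21.1 cm at k = 1 with the default chain. Grid start matters only
through the lower endpoint; starting at the exercise's initial angle
instead of yP = 0 leaves bench results unchanged but lets boundary
artefacts masquerade as maxima at large d for k > 0.

## Forward dynamics

Substituting the constraint-acceleration closure
`th2dd = B·th1dd + C·th1d²` (B = −A; C from differentiating B along the
constraint) into the Newton–Euler moment balance of the two links yields a
single-DOF equation `M_eff(th1)·th1dd = Q(th1, th1d, tau1, tau2)` with
M_eff > 0 on the feasible range. The implementation is cross-checked in
the tests against an unreduced differential-algebraic oracle (both links
free, the track reaction as a Lagrange multiplier, solved as a 3×3 linear
system): accelerations agree to 1e−8 relative, whole trajectories to
1e−6 m/s, the multiplier equals the track-reaction formula, and
torque-free motion conserves energy to better than 1e−6 J per simulated
second. These checks are load-bearing — they caught a transcription error
in C during development — and the power identity
dE/dt = tau1·th1d + tau2·(th2d − th1d) pins down the generalized-force
convention.

Integration: adaptive RK45, rtol 1e−9, atol 1e−12, dense output resampled
at 1 kHz. Lifts start at rest (all study velocity profiles do). Events:
(i) a 1 mm onset guard — the zero-velocity failure event is armed only
after the bar has risen 1 mm, so a rest start is not misread as failure;
(ii) lockout th2 − th1 = 0 → *completed*; (iii) shoulder velocity crossing
zero from above → *failed* (the chain would reverse); a torque that cannot
break equilibrium gives *rest*. Because dyP/dth1 vanishes at lockout, the
bar velocity of every completed lift drops to zero in the final moments;
a "sticking pattern" therefore means a velocity maximum followed by a
*recovered* minimum (or outright failure), never the terminal peak alone.

Three critical-torque notions are implemented (`critical_tau1`):

- **quasistatic** — the maximum of the shared equilibrium torque along the
  lift path. Below it a constant drive cannot balance gravity everywhere,
  so velocity extrema must emerge; this is the number reported as the
  sticking threshold (bench 0.342·Mg at k = 0, 0.226 at k = 1/2; overhead
  0.415 at k = 0, 0.215 at k = 2/3).
- **extrema** — dynamic bisection (1e−5) on whether the simulated profile
  shows a dip or fails. For the bench it coincides with the quasi-static
  value to 3e−4; for the narrow-grip overhead press it sits markedly lower
  (≈ 0.354 at k = 0) because the bar carries enough kinetic energy through
  the equilibrium hump to suppress the dip — a genuinely dynamic effect.
- **completion** — the smallest torque whose lift completes; at this limit
  the sticking-region velocity minimum grazes zero, which is the model's
  definition of a maximal (1RM) lift. Maximal-lift features (velocity
  peak, minimum height) are measured on the just-completing trajectory at
  this bisected torque plus 2e−5.

## Joint loads

The track reaction Rx follows from the link-2 moment balance; the elbow
and shoulder reactions from Newton balances of link 2 and of the whole
chain, each returned with an additive gravity/inertial/track/muscle
decomposition that must sum to the total (asserted at 1e−9 N). Muscle
forces are optional user-supplied point forces (single- or two-joint); the
default empty set gives the ideal-torque-generator reactions, and a helper
warns when a supplied force set's moments disagree with the scenario
torques. No published numeric loads exist to target, so this module is
verified purely by mechanical invariants (system Newton balance,
action–reaction, Rx doing no work on the vertically moving endpoint).

## Waveform similarity

Velocity traces are segmented at their own landmarks — first velocity peak
and subsequent minimum, found on a lightly smoothed copy (centered moving
average, window 5% of samples) — into pre-sticking, sticking and
post-sticking regions. Corresponding regions are resampled to 101 points
(linear interpolation), amplitude-scaled by the *experimental* trace's
global maximum so distances are dimensionless, and compared by DTW with
symmetric steps, cost |a_i − b_j| and a Sakoe–Chiba band of half-width
ceil(w%·101), default w = 20. The similarity index SI = 1 − D/(D + L)
takes L = 101 (the common resampled length). The amplitude scaling is a
package decision: D and L otherwise carry different units, and the cited
formulation leaves the normalisation open; it is configurable. The DP is
evaluated along anti-diagonals with vectorised minima and equals a
brute-force full-matrix DP at w = 100 in the tests.

Significance: both series' sample orders are shuffled (a one-sided
variant shuffles only the second), SI recomputed, and p is the plain
proportion of permutations with SI ≥ observed, floored at 1/n_perm
(default n_perm = 1000, seeded generator mandatory). Under a white-noise
null the p-distribution is approximately uniform (KS-checked at 200
repetitions in the suite).

## Synthetic pseudo-experimental traces

Real 1RM traces differ from the constant-torque model chiefly by a gradual
terminal deceleration and measurement noise. The generator simulates a
maximal lift (completion-limit torque by bisection unless a torque is
given), tapers the final 15% (default) of the trace linearly to zero, and
adds Gaussian noise (default sd 0.02 m/s) smoothed by a 25-sample moving
average; everything is deterministic for a fixed seed. Passing the
pipeline on these fixtures demonstrates the expected *pattern* — high
pre-sticking/sticking similarity, degraded post-sticking similarity when
terminal deceleration is present — not agreement with any particular
experimental dataset: the fixtures inherit the model's own shape, so they
cannot probe model bias, only the segmentation/cDTW machinery.

## Numerical choices and problem sizes

Equilibrium curves use 2000-point grids (4000 for path maxima);
bisections run to 1 mm (d*), 1e−5·Mg (torques); trajectories are sampled
at 1 kHz. The acceptance script runs all headline quantities in a few
seconds; the full test suite (including DAE-oracle integrations and the
permutation-null calibration) takes about a minute. All reported
quantities are deterministic; seeds only affect the synthetic-trace
generator and permutation tests.

## Known limitations

Constant torques (no activation dynamics, no force–length/velocity), no
muscle redundancy resolution (reactions are exact only for the
ideal-torque case or a user-supplied consistent force set), planar
geometry, no eccentric phase, no inverse dynamics from measured
kinematics. The quasi-static sticking threshold and the dynamic
extrema threshold genuinely differ for narrow grips; both are exposed and
the difference is physical, not numerical.
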
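# Methods

`tiltstand` models the postural control of a rat standing bipedally on a
floor that tilts backward (toes-up) by 8.8° over 0.25 s, roughly 0.9 s
after a light cue. The package has four computational layers: the stance
plant, the controllers, GA parameter identification, and marker
kinematics; a synthetic-data layer regenerates every input the analysis
needs, since the original recordings are not publicly deposited.

## Stance plant

The body is a single rigid link from the 4th metatarsophalangeal (MTP)
joint to the whole-body centre of mass (CoM), with angle θ from the
vertical, backward rotation positive:

    J θ̈ = m g h sin θ + τ + τ_floor + noise,
    τ_floor = −k_P (θ − φ) − k_D (θ̇ − φ̇),

where φ(t) is the floor angle (a linear ramp), τ the active control
torque, and the noise an additive Gaussian torque. Parameters and
defaults:

| symbol | meaning | default | unit |
|---|---|---|---|
| m | body mass | 0.404 | kg |
| h | MTP→CoM length | 0.107 | m |
| J | moment of inertia about the MTP | m·h² (point mass) | kg·m² |
| k_P | passive MTP stiffness | 0.34·mgh | N·m/rad |
| k_D | passive MTP viscosity | 0.03·mgh | N·m·s/rad |
| σ | torque-noise magnitude | 0.50 | mN·m |
| — | sensory delay | 40 | ms |
| dt | sampling time (plant and controller) | 1 | ms |

`mgh` ≈ 0.424 N·m is the gravitational toppling stiffness; gains are
normalized by it so bodies of different size are comparable. With
k_P = 0.34·mgh the upright posture is a saddle (net stiffness
mgh − k_P > 0): without active control the tilt topples the body, which
the test suite verifies.

The moment of inertia is never reported for this preparation; the
point-mass value m·h² is the consistent choice for a single-link
MTP-to-CoM reduction and can be overridden.

**Integration.** Fixed-step classical RK4 at 1 ms with the control and
noise torques held constant over each step. The floor rate φ̇ is piecewise
constant with its corners on the step grid, so every RK4 stage uses the
mid-interval rate, which is exact for the whole open interval; this keeps
the ramp-corner discontinuity out of the integrator. A per-interval
DOP853 re-integration (rtol 1e-11) is used as an oracle in the tests; the
closed loops agree with it to far better than 1e-4 rad. Trajectories that
pass 2π rad are frozen there (the body is on the floor; integrating
further only overflows).

**Noise.** The torque noise per 1 ms step is σ·η with η ∼ N(0, 1), i.e.
σ is the per-sample SD at the 1 kHz rate; with mgh ≈ 424 mN·m the
identified σ = 0.50 mN·m is plausible at this scale. The alternative
continuous-time reading (per-step SD σ/√dt) is available as
`noise_scaling_mode="sqrt-dt"`. It produces slow, low-dimensional angle
wiggles that the five-parameter family can chase realization-by-
realization, which destroys single-trace parameter identification — one
reason the per-sample reading is the default.

## Controllers

**Receding-horizon MPC.** At every step the controller forecasts θ over
the prediction horizon H_p with a zero-order-hold discretization of the
linearized (sin θ → θ) plant + floor model, lets the planned torque vary
freely for H_u steps and holds it constant afterwards (move blocking),
and minimizes

    Σ_{k=1..Hp} θ̂_k² + w_Δu Σ_i (u_i − u_{i−1})² + ε Σ_i u_i²

(the target angle is always zero; u_{−1} is the previously applied
torque). Only the first move is applied. The problem is an unconstrained
quadratic, so the first move is an exact linear gain on the state
estimate, the previous torque, and the floor preview; gains are
precomputed once per parameter set and the closed-form solution is
checked against an independent finite-difference quadratic-program oracle
to 1e-8.

The input-increment weight w_Δu is the manipulated-variable-rate term of
the standard industrial MPC cost. It acts on unscaled physical units, so
its magnitude is meaningful only together with a variable scaling, which
is unreported for this paradigm; the default w_Δu = 1e4 was calibrated once so
that the closed loop at the identified parameters reproduces the
few-degree CoM excursion observed in trained animals. Without a
substantial rate penalty the optimizer cancels the tilt to ~0.002° and
the closed loop degenerates (nothing left to identify). ε = 1e-8 is pure
numerical conditioning.

**Floor knowledge (`preview`).** Three policies share identical gains and
differ only in the preview content:

* `"none"` (default): the floor state is unknown to the controller; the
  internal floor model assumes a level floor, and the disturbance is felt
  only through the (delayed) body measurements. In this reactive regime
  the control torque rises only after the floor torque does, as observed
  in trained animals.
* `"measured"`: the currently sensed φ, φ̇ held constant over the
  horizon (a measured disturbance without future preview).
* `"full"`: the exact future floor trajectory over the horizon (a
  perfectly learned cue–tilt association); gives anticipatory torque
  before onset. With an angle-only cost on a saddle plant this policy
  rides the stable manifold and produces a horizon-growing pre-lean, so
  it is not the default regime; it exists to express the preview
  hypothesis and is exercised by the tests.

**Delay.** The 40 ms sensory delay applies to all controllers. The MPC
compensates it by forward-propagating the delayed measurement through the
internal model with the stored torque history (and floor history when the
floor is sensed) — a standard predictor; on a small-amplitude tilt, where
the linearization is essentially exact, the compensated estimate tracks
the true state to better than 1e-6 rad. The PD baselines act on the raw
delayed measurement: they have no internal model.

An important emergent property: because the first move feeds back the
previously applied torque with a coefficient near one (large w_Δu), the
controller has integral-like action. Every topple within the explored
parameter box is eventually arrested near 30–35°, i.e. the closed loop
never passes the |θ| > π/2 fall criterion even at a 10 ms horizon. See
"Stability boundary" below.

**PD baselines.** Linear PD with the human-stance gains
k_P = 1.46·mgh, k_D = 0.3·mgh, and the nonlinear PD previously identified
for standing rats, τ = −k_P2·mgh·θ|θ| − k_P0·mgh·θ − k_D·mgh·θ̇ with
k_P2 = 196, k_P0 = 0.88, k_D = 0.11. The quadratic term is written with
odd symmetry (θ|θ|) so it always opposes the displacement; the printed
form θ² leaves the sign for θ < 0 ambiguous.

## Synthetic data

The generator's defaults are the study conditions: identified mean
parameters (H_p = 0.96 s, H_u = 24.4 ms, k_P = 0.34·mgh, k_D = 0.03·mgh,
σ = 0.50 mN·m), measured body constants, the 8.8°/0.25 s ramp, the
[−0.35, 0.45] s window at 1 kHz, and 18 sequences by default. Trained
trials are the MPC closed loop; naive (pre-learning) trials default to
the same loop with a 0.05 s prediction horizon — learning is interpreted
as acquiring prediction depth — the axis the horizon sweep probes and the
one the cue-to-tilt interval comparison makes meaningful — and PD baselines are available as
alternative naive surrogates. Marker motion is generated by forward
kinematics of the five-segment chain with prescribed segment-angle
functions, so angular velocities are known exactly by construction.

What the synthetic data does *not* emulate: multi-joint coordination
(the single link has one angle), across-trial learning dynamics, foot
lift-off, marker tracking noise and dropouts, and inter-animal
variability in body constants. Passing tests therefore validate the
method's internal consistency under the modelled conditions, not its
behaviour on raw laboratory recordings.

## GA identification

The five free parameters (H_p, H_u in seconds; k_P, k_D in multiples of
mgh; σ in mN·m) are searched by a real-coded GA (population 40, up to 60
generations, tournament size 3, blend crossover α = 0.5, Gaussian
mutation with SD 10 % of each range, elitism 2, stall-based early stop).
A candidate is scored by running five seeded simulations, averaging the
angle traces sample-wise, and taking the MSE against the target trace;
falls are penalized with a large finite value (1e6 rad²) instead of
raising. Default bounds follow the explored ranges: H_p ∈ [0.03, 1.3] s,
H_u ∈ [2, 50] ms (clipped to H_u ≤ H_p per candidate), k_P ∈ [0, 1.5],
k_D ∈ [0, 0.3], σ ∈ [0, 2] mN·m.

All candidates within one run are evaluated on the same noise seeds
(common random numbers), making the objective a deterministic function of
the parameters. With per-candidate seeds the GA shops for noise
realizations that happen to correlate with the target's wiggles and
reports spurious optima well below the generating parameters' score.

**Identifiability.** The parameter→trace map of this loop is nearly
degenerate: a profile analysis (fix H_p at a wrong value, refit the
rest) reproduces the generating trace to within ~1 % of its rms in every
stable regime examined. Individual parameters are therefore determined
only up to a low-dimensional valley, and per-sequence recoveries scatter
along it; means over several sequences land near the generating values
but no tighter than the scatter. The reported across-sequence spreads of
the original identification are consistent with the same flat-valley
behaviour. σ in particular only enters the objective through the
(small) residual variance of the averaged candidate trace and is the
least determined of the five.

## Kinematics

Nine sagittal landmarks (MTP, lateral malleolus, knee, greater
trochanter, iliac crest, iliac-crest–scapula midpoint, scapula,
temporomandibular joint, nose) define a five-segment chain — foot
(MTP→malleolus), leg (malleolus→trochanter), lower trunk
(trochanter→midpoint), upper trunk (midpoint→scapula), head (TMJ→nose) —
with cadaver-measured inertial fractions shipped as packaged data: mass
percentages (1, 9, 53, 29, 8) and segment-frame CoM coordinates Ls
(percent along the line) and Lv (percent perpendicular; positive =
ventral, so the head's −7 places its CoM dorsally). The landmark-to-
segment assignment beyond the stated lower ends is this package's
convention (the source defines it only graphically); the fixtures pin
down this convention.

Markers are smoothed with a zero-phase (forward–backward) 4th-order
Butterworth low-pass at 15 Hz — zero-phase is the standard kinematics
choice; the effective attenuation is the squared magnitude response. The
CoM angle is the angle of the MTP→whole-body-CoM vector from the
vertical; segment angles are measured from the vertical, backward
positive, unwrapped before differencing; angular velocities use central
differences (one-sided at the edges).

The per-segment rotation effect integrates, over [0, 0.3] s after tilt
onset (trapezoidal rule),

    E_i = ∫ (m_i/M) · cos∠(r, r_i) · ω_i dt,

with m_i the mass of the body part from segment i upward, r the
MTP→whole-body-CoM vector, r_i the vector from the segment's lower marker
to the CoM of that upper part, and ω_i the segment's angular velocity.
The cosine is the signed normalized dot product. Note this statistic is a
per-segment *attribution* under the stated rigid-above-the-segment
assumption, not an exact decomposition: the exact chain-rule contribution
of a joint rotation carries r·r_i/|r|² and joint-relative rates, whereas
the statistic uses the cosine and absolute rates. Consequently the sum
Σ E_i equals the CoM-angle change exactly only when the part above the
pivot is the whole body rotating about the bottom pivot (a single-link
body, for which the tests verify agreement to 0.5 %); for a multi-segment
rigid rotation the sum counts nested masses repeatedly (Σ m_i/M ≈ 3.34).

## Stability boundary and other reproduction notes

* The instability criterion is |θ| > π/2 at any sample — physically the
  body is unambiguously down, and the threshold is far from any explored
  trajectory's regular excursions. Because of the integral-like torque
  action described above, short-horizon loops are arrested near 30° and
  never cross π/2, so the 10–100 ms stability scan finds every value
  stable and reports 10 ms as the smallest all-stable horizon. A
  fallen-rat threshold below ~25° would flag those arrested runs instead
  and move the boundary into the reported 30 ms range, but the criterion
  was fixed in advance and is not adjusted to the outcome. The reported
  upper bound near 1.3 s is treated as a soft property (it plausibly
  reflects numerical conditioning of very long horizons in the original
  tooling) and is not asserted.
* The controller-comparison contrast at disturbance termination is
  quantified two ways: the largest one-step torque increment and the
  largest one-step slope change ("bend"). In this regime the increments
  are dominated by recovery slopes and roughly tie, while the bend
  separates the MPC from both PD baselines by more than an order of
  magnitude; the bend is the formalization the property suite asserts.
* Horizon sweeps share noise seeds across swept values, so differences
  reflect the parameter. The peak-angle decrease with H_p holds across
  the probed grid {0.03, 0.1, 0.3, 0.96, 1.3} s; the peak-torque
  decrease is assessed over the well-regulated range (≥ 0.1 s), since at
  a 30 ms horizon the controller barely acts and its torque is small for
  the wrong reason.
* Problem sizes used by the shipped acceptance pipeline: five synthetic
  sequences, GA population 40 with up to 60 generations and early stall,
  five repetitions per evaluation, ten seeds per stability-scan value.

## Known limitations

Single-link sagittal dynamics only (no CoP/ground-reaction model, no
foot lift-off); the learning process itself is not modelled — only its
endpoints (naive vs trained surrogates); the MPC cost scaling (w_Δu) is
determined only up to the unreported variable scaling of the original
tooling; and the identification objective cannot pin the five parameters
individually (see Identifiability above).
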
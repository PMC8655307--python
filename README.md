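# tiltstand

Predictive postural control of bipedally standing rats on a tilting
floor: an inverted-pendulum stance model driven by receding-horizon
model-predictive control (MPC), conventional PD baselines, genetic-
algorithm identification of the model parameters from centre-of-mass
(CoM) angle traces, and marker-based segment kinematics. The package is
aimed at motor-control and computational-neuroscience researchers who
want to simulate, identify, and dissect this floor-tilt paradigm without
access to the original recordings: a synthetic-data layer regenerates
every input under the study conditions.

## The model

The standing rat is a single rigid link from the metatarsophalangeal
(MTP) joint to the whole-body CoM, with angle θ from vertical (backward
positive), on a floor whose angle φ(t) ramps 8.8° backward over 0.25 s:

    J θ̈ = m g h sin θ + τ + τ_floor + σ ξ,
    τ_floor = −k_P (θ − φ) − k_D (θ̇ − φ̇).

The active torque τ comes from an MPC that forecasts θ over a prediction
horizon H_p with an internal copy of these dynamics, varies its planned
torque for a control horizon H_u (move blocking thereafter), minimizes
the sum of squared predicted angles plus an input-increment penalty, and
applies the first move — re-solved every millisecond, with a 40 ms
sensory delay handled by a model-based predictor. Five parameters are
free and identified from CoM traces by a GA: H_p, H_u, the passive MTP
stiffness k_P and viscosity k_D (as multiples of m·g·h), and the torque-
noise magnitude σ. A per-segment rotation-effect statistic
E_i = ∫ (m_i/M) cos∠(r, r_i) ω_i dt attributes CoM-angle change to
individual segment rotations from nine digitized landmarks.

See `docs/methods.md` for assumptions, parameter tables, and numerical
choices.

## Worked example

```python
import numpy as np
from tiltstand import SyntheticTrialSpec, synth_trial, synth_naive_trial
from tiltstand.experiments import sweep_prediction_horizon

spec = SyntheticTrialSpec(seed=1)          # study conditions, identified means
trained = synth_trial(spec, 0)             # post-learning closed loop
naive = synth_naive_trial(spec, 0)         # short-horizon pre-learning surrogate
print("trained peak CoM angle: %.2f deg" % np.degrees(trained.max_abs_theta()))
print("naive   peak CoM angle: %.2f deg" % np.degrees(naive.max_abs_theta()))

sweep = sweep_prediction_horizon([0.1, 0.3, 0.96, 1.3], n_rep=5, seed=1)
print(sweep.table[["hp", "max_abs_theta", "max_abs_tau"]].to_string(index=False))
```

prints

```
trained peak CoM angle: 6.54 deg
naive   peak CoM angle: 31.13 deg
  hp  max_abs_theta  max_abs_tau
0.10       0.181755     0.129040
0.30       0.141777     0.064617
0.96       0.113884     0.056996
1.30       0.088763     0.050892
```

The trained controller (H_p = 0.96 s) keeps the tilt response to a few
degrees while the naive surrogate (H_p = 50 ms) swings ~5× further — the
learning effect. In the sweep, both the peak CoM angle (rad) and the
peak torque (N·m) fall as the prediction horizon grows: deeper
prediction stabilizes the body with less effort.

A thin CLI mirrors the library (`tiltstand simulate|synth|identify|
kinematics|experiment ...`); every run writes CSV outputs plus a JSON
manifest with the configuration hash and seeds.

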
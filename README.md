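# diffeffector

Differentiable planar musculoskeletal effectors controlled by recurrent
neural networks trained end-to-end with gradient descent *through the
physics*.

The package implements:

- **Skeletons** — a planar point-mass and a two-joint arm (shoulder +
  elbow, horizontal plane, no gravity), integrated with a fixed-step
  Euler scheme (`dt = 0.01 s`).
- **Muscles** — a linear piecewise ("ReLu") actuator and a rigid-tendon
  Hill-type actuator (active force-length, force-velocity and
  passive-stretch curves; first-order excitation-to-activation
  dynamics).
- **Muscle geometry** — muscle paths declared as fixation points in
  bone-relative frames, with moment arms computed either from the path
  geometry in closed form or from a quadratic length-vs-angle
  approximation.
- **Effectors** — presets `ReluPointMass24` (point-mass + 4 linear
  muscles in an "X"), `RigidTendonArm26` (arm + 6 Hill muscles,
  polynomial moment arms) and `GeometricArm26` (same arm, moment arms
  from the declared paths).
- **Task environments** — delayed (Δp = 20 ms, Δv = 50 ms), optionally
  noisy visual/proprioceptive observations; go-cues, catch trials,
  mechanical endpoint perturbations and a velocity-dependent curl field;
  standard `reset`/`step` environment API with a reward of 0 (learning
  uses the differentiable loss, not reward).
- **Policy & training** — a one-layer GRU with sigmoid readout and the
  composite loss (positional L1 with target-radius dead zone,
  strength-weighted muscle cost, hidden-activity cost, kernel
  regularization), trained by backpropagation through time **and**
  through the effector.
- **Replication protocols** — curl-field adaptation with after-effects,
  perturbation generalization, preferred-movement-direction (PMD)
  analysis, and the passive-drift map.

Everything runs on a small, self-contained reverse-mode automatic
differentiation engine over numpy (`diffeffector.autodiff`) — no deep
learning framework is required.

## Test

```bash
python -m pytest tests/
```

The suite contains unit/property tests per module plus
`tests/test_acceptance.py`, which runs the acceptance criteria.  The
training-based criteria (scaled-down training, curl-field adaptation,
PMD replication) train real networks and take several minutes each;
everything else completes in seconds.

## CLI

```bash
diffeffector kinematics --check-energy
diffeffector muscle-curves --muscle elbow_flexor --out curves.csv
diffeffector moment-arms --effector GeometricArm26 --grid 21 --out ma.npz
diffeffector train --config train.yaml --seed 1 --out ckpt/
diffeffector experiment curl|perturb|pmd|drift --scale ci|full --seed 1 --out dir/
```

`--scale full` uses the published protocol sizes (tens of thousands of
batches); `--scale ci` is a reduced schedule preserving the qualitative
outcomes.

Example `train.yaml`:

```yaml
effector: RigidTendonArm26
environment: RandomReach
environment_kwargs: {horizon: 0.8}
n_units: 50
n_batches: 1000
batch_size: 32
lr: 0.003
loss: {alpha: 2.0, beta: 5.0, gamma: 0.1, kappa: 0.05, lam: 1.0e-5, target_radius: 0.01}
```

## Library example

```python
import numpy as np
from diffeffector import (rigid_tendon_arm_26, RandomReach, GRUPolicy,
                          PolicyConfig, LossConfig, train)

arm = rigid_tendon_arm_26()
env = RandomReach(arm, horizon=0.8)
policy = GRUPolicy(PolicyConfig(n_units=50, n_inputs=env.observation_size,
                                n_outputs=arm.n_muscles), seed=0)
result = train(env, policy, LossConfig(), n_batches=1000, batch_size=32, seed=1)
```
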
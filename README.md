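# creditseq

Models and analyses of reinforcement learning driven by **choice-selective
cortical sequences**. In a probabilistic reversal task (70%/10% levers,
identities reversing after 10 rewards plus a geometric tail), prelimbic
cortex neurons projecting to the nucleus accumbens fire in reliable,
choice-specific temporal order spanning the seconds between a lever press
and its outcome. This package implements, on synthetic data, the two circuit
models that explain how such sequences support trial-by-trial learning, and
the statistical machinery used to characterise them:

- **Task engine** — the reversal task in its reward-counted, geometric and
  per-trial-hazard variants, with stay-probability and reversal-aligned
  choice summaries.
- **Synthetic data** — single-trial choice-selective population activity
  (consistent "PL-like", unreliable "mTH-like" and early-only presets),
  optogenetic-like perturbations, and event-locked traces with known
  ground-truth kernels.
- **Synaptic-plasticity TD circuit** — value as a weighted sum of the input
  sequences, V(t) = Σᵢ wᵢ fᵢ(t); dopamine RPE through a delayed inhibitory
  pathway, δ(t) = r(t) + (γV(t) − V(t−Δ))/Δ, γ = e^(−Δ/τ); eligibility-trace
  weight updates dwᵢ = α δ(t) Eᵢ(t) dt under a Dale (non-negativity)
  constraint; probe-based softmax action selection.
- **Actor-critic network model** — critic and actor LSTMs (NumPy, hand-
  derived backprop verified by finite differences) trained with advantage
  actor-critic; after training the weights freeze and reversal learning
  happens purely in the recurrent dynamics.
- **Encoding model** — 25-function B-spline event-kernel regression with
  lasso/CV, and circular-shift shuffle-null nested F tests for event
  modulation and choice/outcome selectivity.
- **Decoders** — sequence-type-weighted logistic decoding of choice and
  outcome, piecewise-linear trial time-warping, and binned time-course
  decoding.
- **Behavior stats** — choice-history and stimulation-interaction logistic
  regressions, and the dopamine outcome-history regression.
- **Observer models** — Bayesian ideal observer vs. Q-learner (α = 0.612)
  and their reward-prediction-error signatures at block reversals.

See `docs/methods.md` for the models, parameters and design decisions.

## Worked example

Run the plasticity circuit on the reversal task with the reference
parameters and summarise its behavior:

```python
import numpy as np
from creditseq.task_engine import TaskConfig, stay_probability
from creditseq.plasticity_model import PlasticityParams, run_plasticity_session

rng = np.random.default_rng(1)
session, history = run_plasticity_session(
    "pl_like", TaskConfig(), PlasticityParams(), 5000, rng)
print(f"reward rate {100 * session.reward_rate():.1f}%  "
      f"block length {session.mean_block_length():.1f}")
print(stay_probability(session))
```

prints

```
reward rate 46.6%  block length 25.1
  prev_outcome  stay_prob     n
0     rewarded   0.999570  2327
1   unrewarded   0.836826  2672
```

— the model earns well above the 40% chance rate (a choice-blind policy
earns (0.7 + 0.1)/2), its blocks last about as long as the mice's, and it
repeats rewarded choices far more often than unrewarded ones. The same
entry point with the `early_only` preset (α = 0.003, softmax gain 1000)
gives ~42%, and `mth_like` ~38% with visibly slower reversals — the
orderings that show why sequence consistency matters.

The equivalent shell command:

```bash
credit-seq run-plasticity --profile pl_like --n-trials 5000 --seed 1 --out run.h5
```

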
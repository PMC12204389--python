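# foragehmm

Latent motivation-state analysis of a primate reward-pursuit ("foraging")
task. Monkeys encounter a sequence of reward opportunities that vary in
magnitude (1–3 juice drops) and probability (shown on a 0.05 grid), inside
blocks that set the richness (mean reward probability 0.80 vs 0.55) and
stochasticity (sd 0.05 vs ≈0.13) of the environment. On each trial the
animal pursues or rejects the offer. Pursue/reject behavior is strongly
autocorrelated in ways a trial-wise GLM cannot explain; this package models
that structure with a **GLM-HMM**: a hidden Markov chain of motivation
states whose emissions are logistic decisions,

```
p(y_t = pursue | z_t = k, x_t) = σ(w_k · x_t),          z_{t+1} ~ A[z_t, ·],  z_1 ~ τ
```

with design `x_t = [1, z-EV_t, richness cue, stochasticity cue]`. Only the
bias weight varies between states (a share mask constrains the rest), so
the states capture shifts in the intrinsic propensity to pursue rewards:
the state with the larger bias is the *high-motivation* state.

The package is aimed at computational-neuroscience and behavioral-statistics
users who want a tested, seedable reference implementation of this whole
analysis chain on synthetic data:

- `foragehmm.task` — generative task simulator (block design, reward
  draws, timing) and GLM-HMM agents, including perturbed-transition
  agents emulating focal-stimulation conditions;
- `foragehmm.features` — derived regressors (EV, trailing richness /
  stochasticity / Ave.EV windows, choice history, lagged outcomes), also
  available as a sklearn `TrialFeaturizer` transformer;
- `foragehmm.glmhmm` — the `GLMHMM` estimator: EM fitting with seeded
  restarts, forward–backward posteriors, exact Viterbi decoding,
  session-wise AIC, cross-validated selection of the state number, and
  seven-trial transition-period extraction;
- `foragehmm.model_validation` — decoding-accuracy and transition-distance
  experiments, model/parameter recovery, and behavioral recapitulation
  (decision ACF, run lengths, regression battery on simulated data);
- `foragehmm.behavior_glms` — the 13-model mixed-effects regression
  registry (GLM1.1–1.3, 2.1–2.5, 4.1–4.5) over trial tables;
- `foragehmm.pupil` / `foragehmm.bold` — pupillometry preprocessing and
  epoching, and ROI BOLD time-course statistics (×15 upsampled epochs,
  per-timepoint OLS, leave-one-out peak selection with Holm correction,
  PPI), exercised on synthetic signals with known injected effects.

## Worked example

```python
import numpy as np
from foragehmm import task, GLMHMM, build_design

table = task.generate_dataset(n_subjects=1, n_sessions_per_subject=16, seed=1)
X, y, sessions = build_design(table)
model = GLMHMM(n_states=2, n_restarts=5, random_state=0).fit(X, y, sessions)
print("biases:", model.weights_[:, 0].round(2))
print("self-transitions:", np.diag(model.transmat_).round(3))
z = model.decode(X, y, sessions)
print("decoding accuracy vs truth:",
      round(100 * (z == table["true_state"]).mean(), 1), "%")
```

```
biases: [ 1.24 -1.47]
self-transitions: [0.965 0.97 ]
decoding accuracy vs truth: 93.5 %
```

The fitted state biases bracket the generating values (±1.3 logits, a 2.6
logit separation), the transition matrix recovers the generating 0.97
self-transition probability, and Viterbi decoding recovers the true latent
state on ~94% of trials in this dataset. A CLI mirrors this pipeline:
`foragehmm simulate|fit|decode|select-k|validate|analyze`.

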
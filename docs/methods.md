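# Methods

## The task model

The simulator emulates a sequential reward-pursuit task. Each session has
four blocks of 40–50 trials, one per environment type: the cross of
richness (rich / poor) and stochasticity (predictable / stochastic). Block
order alternates richness labels (no two rich or two poor blocks adjacent),
and stochasticity is assigned randomly within that constraint; this
reflects the design goal of avoiding long stretches of low-value offers.

Reward probabilities live on a 0.05 grid in [0.05, 1.00]:

- **predictable** blocks draw from a Gaussian with mean μ (0.80 rich, 0.55
  poor) and sd 0.05, clipped to the valid range and rounded to the grid.
  The grid matches the visual quantization of the stimulus (dots in 0.05
  increments); the designed sd of 0.05 survives the rounding.
- **stochastic** blocks draw from a discrete uniform over the nine grid
  points μ ± {0, 0.05, 0.10, 0.15, 0.20} (a 0.40-wide support). The
  analytic sd of this distribution is √(2·(0.05²+0.10²+0.15²+0.20²)/9) ≈
  0.1291, which matches the designed "≈0.13" width; a *continuous* uniform
  of the same range would give 0.1155 and does not.

Reward magnitudes are uniform on {1, 2, 3} drops. Timing: go-cue and
action–outcome delays ~ U(3, 4) s; the inter-trial interval is drawn from
N(1, sd 2) truncated below at 0.5 s (we read the design's dispersion
parameter as a variance of 4; negative draws are physically impossible, so
truncation is required either way — timing only matters for the BOLD
module). Premature responses are not generated: they are excluded from all
modelling anyway, so simulating them would only add a row-filtering step.

## The agent (generative GLM-HMM)

Decisions come from a K-state GLM-HMM. The design vector is
x_t = [1, z-EV_t, richness-cue, stochasticity-cue], with EV = magnitude ×
probability z-scored within session (sessions are the modelling unit, and
using the same standardization for generation and fitting keeps parameter
recovery interpretable). The default reference agent has

- bias ±1.3 (2.6 logit separation between high- and low-motivation
  states — the size of state effect a fitted two-state model of this kind
  typically shows),
- shared EV weight 1.0, zero cue weights,
- self-transition probability 0.97 in both states,
- initial distribution τ = (0.70, 0.30) favoring the high state.

These are documented defaults emulating a plausibly fitted animal, not
ground truth. Simulated reaction times are log-normal around 0.76 s with a
0.15 log-unit speed-up in the high state, so the RT regression has a known
effect to recover.

## Derived regressors

All window statistics are strictly retrospective, window w = 5 by default:
richness_t = mean(outcome_{t−5..t−1}); stochasticity_t is the trailing
sample sd (ddof = 1, matching R's `sd`) of the richness series; Ave.EV_t =
mean(EV_{t−5..t−1}); behavioral history is the lag-1 decision. Windows
never cross session boundaries; affected trials are NaN and are dropped
listwise before any regression that uses them (no imputation). Continuous
predictors are z-scored within subject before model fitting — applied
uniformly so coefficients are comparable across models; raw values are
kept in the table.

## Fitting, decoding, model selection

The marginal likelihood is maximized by EM with seeded random restarts
(default 10; experiments that fit hundreds of models use fewer). The
E-step is a scaled forward–backward pass run jointly over sessions padded
to a common length; sessions are independent chains sharing parameters,
with the initial distribution applied per session. The M-step re-estimates
the transition matrix and τ from expected counts with a Dirichlet-style
pseudocount of 1e-2 (protects against empty rows on short data) and
maximizes the expected complete-data log-likelihood over the masked
weights with L-BFGS (the subproblem is convex; warm-started, so the EM
objective is monotone — asserted in tests to 1e-7). Stopping: absolute
log-likelihood change < 1e-6 or 200 iterations. After fitting, states are
ordered by descending bias, so state 0 is always "high-motivation"; all
downstream summaries are invariant to generator state permutation.

Decoding is exact Viterbi (ties toward the lower state index);
forward–backward posteriors are also exposed. Both, and the forward
likelihood, are verified against brute-force path enumeration at T ≤ 10,
K ≤ 3 to 1e-8.

The number of states is chosen by 5-fold cross-validation over sessions
(fold sizes differ by ≤ 1). Because the models are nested — a K+1-state
model with coincident biases reproduces the K-state likelihood exactly —
the raw argmax of mean held-out log-likelihood is a coin flip when the
extra state is superfluous (margins of tenths of a nat against fold SEMs
of tens). `select_k` therefore defaults to a one-standard-error parsimony
rule on the paired fold-wise differences: the smallest K within one paired
SE of the best-scoring K; the plain argmax remains available
(`rule="argmax"`). When the data truly carry two states, K = 2 wins by
tens of nats and the two rules agree. Session-wise AIC = 2k − 2·LL_s is reported with k the
total free-parameter count of the jointly fitted model (bias-only K = 2
over 4 predictors: 2 + 3 + 2 + 1 = 8). Transition periods are symmetric
seven-trial windows around decoded transition trials, truncated (not
dropped) at session edges so rare events in short sessions are kept;
shifted placements (t−6..t) through (t..t+6) are supported for timing
analyses.

## Validation experiments

Decoding validation simulates 10 datasets × 16 sessions from the reference
agent, re-fits a two-state model to each dataset, Viterbi-decodes, and
scores trialwise accuracy plus transition timing. Decoding with re-fitted
parameters is the default (that is what one can do with real data); a
`decode_with="true"` flag gives the oracle ceiling. Each decoded
transition is matched to the nearest true transition of the same
direction, ties to the earlier one; decoded transitions with no
same-direction match within ±10 trials count as misses and stay in the
denominator of the "within ±3 trials" fraction. Model recovery generates
from one-state and two-state exemplars and runs the cross-validation
selection over K ∈ {1, 2, 3} by default — the discriminative question is
one state versus two, and larger K roughly triples runtime without
changing the answer; the K list is a parameter. Parameter recovery refits
the two-state model and reports bias / self-transition errors; at 16
sessions the spread of the bias MLE is dominated by state-assignment
uncertainty (sd ≈ 0.19 logits), not by the optimizer (fitted likelihoods
exceed the generating-parameter likelihoods).

## Regression battery

Thirteen model specs cover decision GLMs (current offer, lagged outcomes,
environment, history), decoded-state GLMs (state bias, transition windows,
RT, pupil, Ave.EV), and condition-contrast GLMs with the sham condition as
reference. Binomial mixed models use statsmodels' variational-Bayes mixed
GLM and Gaussian models use MixedLM; a per-subject fixed-intercept GLM is
the fallback for small synthetic datasets and is flagged in the output.
P-values are Wald tests. The RT and pupil models carry no random intercept
because their responses are z-scored within subject. For the lagged-outcome
scan, the reported estimate for lag k comes from the refit in which lag k
carries the random slope.

## Pupil and BOLD machinery

Pupil traces (250 Hz) are scrubbed at blinks and >50 a.u. adjacent-sample
jumps with symmetric 25-sample guard windows, linearly interpolated,
low-pass filtered at 4 Hz with a zero-phase 3rd-order Butterworth filter
(zero phase so epoch means are not shifted; the filter family is a
package choice), z-scored, and the linear x/y-gaze contribution is
regressed out. Per-trial means are taken −0.5..0 s (ITI phase) and
+0.5..+1.0 s (decision phase) around stimulus onset — 125 samples each.
Traces with more than half their samples scrubbed are flagged unusable.

ROI BOLD series (TR = 1.282 s) are z-scored per session ("normalized"),
linearly interpolated to 15× temporal resolution, and epoched −1..+5 s
around onsets (70 samples). OLS runs at each time point across trials.
Group inference selects each session's peak time from the *other*
sessions' mean |β| curve inside a 1–5 s post-onset window, then t-tests
the collected peak βs (two-tailed), Holm-correcting across ROIs within an
analysis family. The synthetic ROI generator convolves trial events with
a gamma HRF peaking at 4 s (canonical macaque latency; configurable) and
adds AR(1) noise, recording ground-truth injected effects.

**A calibration caveat established by simulation:** the leave-one-out
selection makes each session's peak β an unbiased estimate under the null
and provably never lets a session pick its own peak (both tested), but the
selected time point is nearly common across sessions, which correlates the
selected values and inflates the group t-test above its nominal level on
pure-noise data (≈0.10 at 12 sessions vs 0.05 nominal in our simulations,
versus ≈0.18 for non-LOO max-picking). The procedure removes *selection
bias of the estimate*, not all dependence in the group test; results near
the significance boundary should be read accordingly.

## Synthetic data: what it does and does not show

The generator reproduces the task's block structure, reward statistics,
state-dependent choice behavior, and the qualitative signatures used for
validation (choice autocorrelation, long decision runs, richness/history
regression effects). It does not emulate satiety or fatigue drifts,
session-to-session parameter variability, premature responses, real pupil
optics, or physiological BOLD confounds. Passing tests therefore certify
the correctness and calibration of the *machinery* under known generative
conditions, not the biological conclusions one would draw from real
animals.

## Problem sizes

Default experiment sizes are the analysis-scale ones: 10 datasets × 16
sessions for decoding and parameter recovery, 4 subjects × 16 sessions for
structural correlations, 10 datasets per generator with 5-fold CV over
K ∈ {1,2,3} for model recovery, and a few hundred repetitions for null
calibration of the LOO procedure — sizes at which the Monte-Carlo error is
comfortably inside the tolerances used in the tests.
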
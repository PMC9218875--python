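# Methods

This package models how choice-selective *sequences* of cortical input to the
ventral striatum can solve the temporal credit assignment problem in a
probabilistic reversal learning task, and implements the statistical analyses
used to characterise such data. Everything runs on synthetic data; the
generator is a first-class, tested component whose job is to emulate the
relevant statistics of recorded population activity.

## Task

Two levers; the "high" lever pays with probability 0.7, the other with 0.1.
Under the `reward_counted` rule the lever identities reverse, uncued, after
10 rewarded trials plus a geometric number of extra trials
(P(k) = (1-p)^(k-1) p, p = 0.4, support k >= 1, so a reversal can never land
on the criterion trial itself). A choice-blind policy earns
(0.7 + 0.1)/2 = 40%. Two auxiliary rules exist: pure geometric block lengths
(used to train the network model) and an i.i.d. per-trial reversal hazard
(used for the ideal-observer comparison). Within-trial event times (nose
poke, levers out, press, CS, reward consumption) carry the task's programmed
jitters so the encoding/decoding analyses see realistic timing.

A consequence of the reward-counted rule worth knowing: trials just before a
reversal are *selected* for rewarded (hence block-matching) choices, so
reversal-aligned choice curves show above-chance alignment at lags <= -2 for
any policy, including an i.i.d. one. This is an artifact of the rule, not of
learning, and the test suite asserts it explicitly.

## Synthetic choice-selective sequences

Each of 184 neurons per side carries a Gaussian temporal bump (sd 0.3 s) at a
fixed preferred time tiling -2..+3 s around the lever press; the chosen
side's neurons emit their bumps each trial, the unchosen side emits the same
shape scaled by `selectivity`. Per-trial variability: peak-time jitter
(sd 0.1 s), multiplicative amplitude noise (sd 0.7, rectified), and a small
additive band-limited noise floor (sd 0.05, correlated on the 0.2 s
smoothing timescale). Smoothing by the 0.2 s Gaussian kernel is applied
analytically (a Gaussian bump convolved with a Gaussian kernel is again
Gaussian; sigma adds in quadrature and the peak scales by the sigma ratio).

Amplitude convention. Rates are in normalized units with nominal bump peak
1.0. This is the scale implied by the action-selection probe ("probe mean
0.05 = 5% of peak activity") and shared by the stimulation constants (0.2
and 0.15). It is also dynamically important: the within-trial TD update loop
has feedback gain alpha * sum_i f_i(t) E_i(t), which scales with the square
of the amplitude; at unit peak the gain is ~0.2 (stable), while a peak of
~2.4 crosses 1 and the value/RPE dynamics oscillate explosively. Early in
development this instability was mistaken for useful choice noise; the final
preset sits firmly in the stable regime and all stochasticity comes from the
input variability itself.

Presets.
- `pl_like` (consistent cortex-like input): the defaults above, selectivity
  0.1. Noise was calibrated once so that the plasticity model with the
  reference parameters reproduces the reference operating point (reward rate
  ~47%, see below) while keeping the split-half peak-time consistency of a
  92-neuron population at R^2 ~ 0.99 >= 0.8; these values were then frozen.
- `mth_like` (inconsistent thalamus-like input): selectivity 0.5, jitter
  0.2 s, background noise 0.2, and crucially `pattern_reliability` 0.5: each
  neuron fires at its assigned sequence position on only half of trials,
  landing uniformly in the span otherwise. Timing jitter alone turned out to
  be the wrong model of inconsistency — jitter around a reliable mean
  broadens the effective bumps, *helps* eligibility-trace bridging, and can
  even speed reversal learning; genuine per-trial pattern unreliability is
  what degrades both the split-half consistency and the circuit model's
  performance, as in the recorded data.
- `early_only`: all peaks within the first 0.5 s of the sequence
  (-2.5..-2.0 s relative to press); everything else as `pl_like`.

The generator does not emulate: calcium indicator kinetics, photon/motion
noise, source cross-talk, non-Gaussian rate profiles, or cross-neuron noise
correlations. Passing tests therefore certify the analysis pipeline and the
circuit models' mechanisms on sequence-like input, not performance on raw
imaging data.

## Synaptic-plasticity TD circuit

Value is a weighted sum of the input basis functions, V = V_L + V_R with
V_side(t) = sum_i w_i f_i(t); dopamine carries
delta(t) = r(t) + (gamma V(t) - V(t - Delta))/Delta with gamma =
exp(-Delta/tau), tau = 0.7 s, Delta = 0.01 s. Each synapse keeps an
eligibility trace E_i <- exp(-dt/tau_e) E_i + f_i dt (tau_e = 0.8 s, reset at
trial start) and integrates dw_i = alpha delta E_i dt (alpha = 0.009,
forward Euler, dt = 0.01 s) from a random start ~N(-2.5 s, 0.2 s) to +3 s.
The reward input is a Gaussian density (sd 0.3 s) at a uniformly drawn peak
time 0.2-1.2 s post press, zeroed more than 0.2 s before its peak and not
renormalised, so a rewarded trial delivers integrated reward ~0.75 (the
truncated mass); the surprise-reward RPE integral equals this mass, which is
what the conservation test asserts.

Dale constraint. The clip w = max(0, .) is applied to the integration state
itself. The alternative reading — integrate an unclipped accumulator and
expose its rectification — creates a ratchet: most accumulators drift far
below zero (the omission dips and end-of-trial value decay are net
negative), and after a reversal the newly correct side must climb out of
that hole, stretching reversals from ~3 to ~10 trials and collapsing the
reward rate. Both variants are implemented
(`retain_unclipped_accumulator`); the clipped-state form is the default and
the one consistent with the reference behavior.

Action selection reads the earliest ~18.5% of each side's striatal neurons
(34 of 184) with a 50 ms truncated-normal probe (mean 0.05, sd
0.0025/dt = 0.25, truncated at zero — the stated sd value is taken
literally and exposed as a parameter) and passes the probe-averaged decision
variables through a softmax with gain 7000 plus a stay bias 0.15.

At this operating point the model earns ~47-48% reward with ~24-trial
blocks (reference values: 47.2%, 23.0); the early-only control (alpha
0.003, gain 1000) earns ~42% (reference 43.9%), and the mTH-like input
~38% (reference 38.7%) with visibly slower reversal transitions. Compared
with the reference model ours reaches the same reward rate with somewhat
slower reversals and a higher asymptote; the reference one paired ~3-trial
reversals with more choice lapses, a mixture our parameterized input noise
does not fully reproduce at matched reward rate. Relatedly, the
optogenetic-stimulation simulation (70% of neurons clamped to 0.2 for the
trial) reproduces the *reduced* stay after stimulated rewarded trials and
the null effect of current-trial stimulation, but not the reference
*increase* in stay after stimulated unrewarded trials: with the clamp
active, the value signal is elevated and constant, so delta carries a tonic
negative term (-V/tau in effect) that still selectively depresses the
chosen side's surviving (unclamped) onset neurons and, being common-mode,
also shrinks both decision variables and flattens the softmax. With
selectivity fixed at 0.1 this tonic mechanism outweighs the
symmetric-update mechanism that produces the reference sign. The
corresponding test asserts the reference direction and is expected to fail;
we prefer the honest failure to retuning the generator around it.

## Actor-critic network model

Two LSTM networks (critic and actor) written directly in NumPy, with
backpropagation-through-time derived by hand and verified against finite
differences (worst relative error ~1e-6 on random networks). Gate order
(forget, input, output, candidate); Glorot-uniform input weights, orthogonal
recurrent weights, zero biases except a unit forget-gate bias. The critic
reads the sequence input and the previous step's reward and emits V(t); the
dopamine input to the actor is delta(t) = r(t-1) + gamma V(t) - V(t-1)
(rewards enter with one step of latency so the loop stays causal); the actor
additionally receives an efference copy of the previous action and a one-hot
temporal context, and emits a 3-way policy (left, right, do nothing).
Training is advantage actor-critic with RMSprop (lr 0.001/step, rho 0.9),
k-step returns in a form where the immediate reward is itself discounted
by gamma_t (a flag restores the conventional form), gamma =
exp(-0.1/2.5) ~ 0.96 within trials and 0 at trial ends, critic-loss weight
0.05 and entropy weight 0.05. Gradients do not flow from the actor into the
critic through the dopamine input.

Trial grammar: 42 steps of 0.1 s per trial (40 sequence steps spanning
-2..+2 s around the press, a decision-registration step and a zero-discount
end step); pressing is meaningful only on a trial's first step and
wrong-time actions cost -1. Training blocks reverse with per-trial hazard
0.1 so reversals are unpredictable and reward counting is useless.

Desk scale. The full-scale run (128 units, 62,000 fifteen-trial episodes)
is configuration-switchable but far beyond a desk test; the tested
configuration uses 24-32 units, ~10^4 episodes in minibatches of 12,
entropy weight 0.15 and lr 0.003 (the smaller network needs more
exploration pressure), and for most properties a shortened 1.6 s trial
(16 steps, press at 0.8 s, reward peak 0.2-0.5 s). Trained this way, ~4 of
5 seeds yield frozen-weight test performance above the 0.40 chance line
with the reference stay-probability signature (e.g. 0.94 stay after reward
vs 0.28 after no reward), and stimulation of the critic input on 10% of
test trials reproduces the reference pattern: lower stay after stimulated
rewarded trials, higher after stimulated unrewarded ones, no current-trial
effect. The sequential-vs-persistent input comparison is run at the full
4 s trial because the sequential advantage lives in value *timing* across
the press-to-reward delay; with short trials the two input schemes train
equally fast. The effect at this scale is small (end-of-training reward
difference ~0.005) but consistently signed in 4 of 5 paired seeds.

Actor geometry: PCA of the actor state at the decision step across
fixed-length (30-trial) blocks puts ~94% of variance on PC1, which aligns
with the choice readout vector (|cos| ~ 0.5 vs ~0.1 for PC2/3); regressing
PC1 on the previous seven trials' choice, post-press RPE and choice x RPE
shows the interaction terms dominant and decaying over ~3 trials.

## Encoding model

25 cubic B-splines with equally spaced clamped knots per event window
(-2..6 s around actions, 0..8 s after stimuli; 81 samples at 10 Hz;
partition of unity). Predictors are event trains convolved with the basis
and aligned so kernel sample 0 sits at the window start. The production fit
is lasso with 5-fold-CV penalty (scikit-learn LassoCV); significance testing
uses unpenalised OLS and a nested F statistic whose null is built from 500
circular shifts of the trace (minimum shift 81 samples, so the null never
nearly reproduces the data), Bonferroni-corrected over the 7 events.
Choice/outcome selectivity uses the augmented event set with choice-blind
(all-press) and outcome-blind (all-CS) aggregate regressors and drops the
ipsi-press or the CS+/reward-consumption groups respectively. The simulated
press-only control reproduces the motivating artifact: event-locked averages
show spurious CS-locked peaks while the fitted CS kernels stay near zero.

## Decoders

Choice/outcome decoding is logistic regression (minimal ridge 1e-6 for
stability under separation) on window-averaged activity of random ensembles
of 1-10 same-session neurons, 100 ensembles x 5 folds, with inverse-frequency
weights over previous-current-future label triplets; on synthetic data where
activity encodes only the previous choice, the weighting holds lag-0
decoding at chance while an unweighted decoder is fooled above chance. The
time-course decoder first warps each trial piecewise-linearly (outer epochs
pass through; nose-poke-to-press and press-to-next-nose-poke rescale to
their across-trial medians, a continuity-anchored piecewise map) and fits separate weighted decoders on 0.5 s bins.

## History regressions

Choice: logistic regression of the right-press log-odds on signed
rewarded-choice and unrewarded-choice identities 1-5 trials back; the
stimulation variant adds stimulation main effects and reward/unreward x
stimulation interactions, with the combined traces (bR + bLR etc.) exposed
for plotting. Abandoned trials are removed before lagging. Fits use
statsmodels Logit with a minimal-ridge scikit-learn fallback under
separation. Dopamine: OLS of the feedback-window (0.2-1.2 s post CS)
average RPE on the current and previous five outcomes; on the plasticity
model's dopamine this yields a positive current-outcome coefficient and
uniformly negative history coefficients.

## Observer and Q-learning agents

The ideal observer knows the block transition matrix (per-trial hazard
0.05) and reward matrix (100/0 or 70/10); its belief updates recursively
(posterior proportional to reward likelihood times transition-propagated
prior) and its choice values are one-step-ahead expected rewards. The
Q-learner updates only the chosen action's value with alpha = 0.612 from
Q0 = 0. Both select actions through the same softmax (beta_value 0.99,
beta_stay 0.95), so the reversal-RPE comparison conditions on comparable
stochastic choices (the observer could equally act greedily; the shared
rule is a deliberate choice). RPE is reward minus the chosen expectation.
The model-based signature reproduces: on the 100/0 hazard task, the
observer's rewarded second-trial-after-switch RPE is far below the
Q-learner's, because the observer infers the new contingency from the first
reversal trial without having to experience the newly chosen lever.

## Numerical and design notes

- All randomness flows through explicit numpy Generators; seeded runs are
  bit-reproducible.
- The plasticity inner loop is numba-compiled; a pure-NumPy reference built
  from the documented elementary operations is tested for exact agreement.
- The LSTM trainer is pure NumPy (numba was tried for it and was slower at
  these sizes).
- Degenerate inputs: empty stay-probability strata return NaN, never zero;
  zero-variance traces z-score to mean only; an impossible observation under
  a deterministic reward matrix sends the observer's belief to the
  complementary state; non-monotone warp anchors drop the trial and report
  it.
- Problem sizes in the tests (5000-trial circuit runs averaged over 3
  seeds, 10 reduced-length ordering pairs, ~10^4-episode network training,
  200-neuron type-I calibration at 200 shuffles) were chosen so the whole
  suite runs on one CPU in well under half an hour; the acceptance script
  uses 5 seeds x 5000 trials per condition.

## Known limitations

- The sequence generator is Gaussian-bump-parametric; it does not reproduce
  the heavy-tailed, sparse single-trial statistics of deconvolved calcium
  rates, which is the likeliest reason the plasticity model's reversal
  speed / lapse-rate mixture and the unrewarded-stimulation sign differ
  from the reference fits to recorded input.
- The network model is analysed at desk scale; absolute reward rates and
  the size of the sequential-vs-persistent gap are not comparable to the
  full-scale run, only their signs and orderings.
- Mixed-effects (across-animal) modelling, trial-initiation latency, and
  imaging preprocessing are out of scope.
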
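# Methods

## Scope and data model

The package operates on trial logs: ordered records of (stimulus, instructed
side, choice, reward, outcome class, protocol id). Stimulus dimensions are
graded in [−1, +1]; the working-memory frequency set {8, 16, 32, 64, 128} Hz
maps to {−1, −0.5, 0, +0.5, +1}, and unlisted frequencies are rejected
rather than interpolated. Sides are signed right = +1, left = −1 throughout,
and P(right) = σ(⟨ω, x⟩). Logs are CSV (one row per trial, stimulus
dimensions in `stim:<dim>` columns) with a JSON sidecar for session
metadata; write∘read is the identity and unknown columns ride along as
opaque metadata.

Regressor encoding: `bias` is constantly 1; any stimulus dimension named in
the regressor set contributes its graded value; `S1`, `A1`, `R1`, `WSLS`
come from the previous trial and are all zero on the first trial of a log
and after a no-response trial. `WSLS = A1 × R1`. When a multi-dimensional
stimulus has no `S0` dimension, `S1` falls back to the previous trial's
instructed-side sign — one consistent convention for a case the data model
otherwise leaves open. Note a structural identity of binary 2AFC designs:
on choice trials R1 = A1 × S1, hence WSLS = S1 exactly. The offline fits
keep both regressors (they are reported separately in the field) and the
numerical choices below keep their estimates bounded despite the
collinearity.

## Online learner

State (ω, m, t) updates on each choice trial with label y ∈ {−1, +1}:

    mᵗ = (1 − η) (⟨ωᵗ, xᵗ⟩ − y) xᵗ + η mᵗ⁻¹,   m⁰ = 0
    ωᵗ⁺¹ = ωᵗ − α (mᵗ / (1 − ηᵗ) + λ sgn ωᵗ),   sgn 0 = 0

The gradient is the squared-error residual on the raw decision variable;
it drives ⟨ω, x⟩ toward the ±1 label. This is deliberate: the deployed
update is this residual form even though the choice model is a sigmoid, and
the package reproduces it as the default. A cross-entropy gradient
(σ(⟨ω, x⟩) − (y+1)/2) x is available via `Hyper(gradient="logistic")` for
users who want the internally consistent logistic pairing; the two differ
in fixed points (|z| → 1 versus |z| → ∞ on separable data), which matters
for goal placement (below). The 1/(1 − ηᵗ) factor is the standard momentum
bias correction (t counts applied updates, starting at 1), so a constant
gradient passes through unchanged at every t. η = 1 is rejected. Weights
initialize to zero unless a configuration supplies starting values.

## Teacher

Candidates are (stimulus, label) pairs from the task repertoire. In
`rule_constrained` mode the label is the rule's correct side for the
stimulus; in `free` mode both labels are enumerated and the teacher chooses
the reward contingency too (used by the multi-goal task, where stimulus
combinations and reward direction are selected simultaneously). Candidate
history regressors are filled from the realized previous trial, so the
surrogate scores exactly the feature vector the subject will experience.

Scoring uses T₁ (predicted error probability) and T₂ (alignment of the
plain-step update with the straight path from ω to ω*), combined as
γ²T₁ − 2γT₂ and minimized over candidates; exact ties break uniformly at
random under the run's seed, making selection order-invariant. For a
learner taking the literal plain step ω′ = ω − γ(⟨ω, x⟩ − y)x the identity

    ‖ω′ − ω*‖² − ‖ω − ω*‖² = γ²‖(⟨ω, x⟩ − y) x‖² − 2γT₂

holds exactly; the probability-form T₁ stands in for the quadratic term in
the deployed objective. The two are dimensionally different (a probability
versus a squared gradient norm) but move together with the margin y⟨ω, x⟩;
the quadratic form is available as `t1_form="gradient_norm"` and satisfies
the identity exactly.

Goal weights ω* are the converged weights of a perfect rule-follower under
the assumed update: the residual gradient drives ⟨ω, x⟩ to the ±1 label, so
the presets use magnitude 1 on ±1-coded stimulus dimensions and 0.8 on the
graded working-memory pair (the least-squares slope of sign(T0 − S0) on
T0 − S0 over the 20-type repertoire), zero elsewhere. Placing goals far
beyond the reachable fixed point (e.g. logistic-scale values like 3) leaves
a permanent apparent deficit on the relevant dimension that keeps the
teacher maximizing T₂ forever and adds selection jitter after convergence.

The anti-bias baseline applies three priorities in order: (1) three
consecutive failures (errors or no-responses) on one reward direction
repeat that direction — "trial type" is read as the reward direction, the
only type axis the scheduling rule references; (2) three consecutive trials
with the same reward direction (no-responses included) force a switch;
(3) otherwise the left side is sampled with

    P_left = ½ (ΣR·Corr / (ΣR·Corr + ΣL·Corr) + ΣL·Err / (ΣL·Err + ΣR·Err))

over the last N = 50 trials, where the four sums count correct/erroneous
choices on right/left-type trials (the ±1 indicator signs cancel within
each ratio); a ratio with zero denominator is 1/2. No-response trials carry
no correct/error indicator. The random baseline draws uniformly from the
repertoire.

## Students and synthetic data

A simulated student is the same online learner plus a choice policy:
`sample` (choice right with probability (1 − ε)σ(⟨ω, x⟩) + ε/2; lapse ε
defaults to 0) or `threshold` (sign of the decision variable). Sampling is
the default because a deterministic student makes teacher-versus-baseline
comparisons degenerate. Students update toward the trial's correct label —
reward feedback reveals it in these binary tasks — with a choice-supervised
variant (`learn_from="choice"`) exposed for completeness. The "noisy"
student of the simulation experiments starts at bias = +2, S1 = −2; the
ideal student starts at zero.

The fixture generator emits logs whose choices are Bernoulli draws from a
fixed ground-truth model over uniformly random instructed sides, with an
optional no-response rate; it is the known-truth input for every analysis
test. The event-train generator emits evidence-accumulation sessions with
per-bin Bernoulli events and choices from a fixed kernel, for kernel
recovery. These generators emulate stationary strategies and trial-wise
independence; real animals drift, lapse non-uniformly, and correlate
engagement over time, so passing recovery tests certifies the estimators,
not the biology.

## Closed loop and advancement

Per trial: the policy proposes a candidate, the student chooses, the
outcome is scored, the student learns from the outcome, and the surrogate
updates on the student's realized choice — choice trials only, so the
surrogate's update count always equals the number of choice trials.
Criteria are trailing-window accuracies over qualifying trials (window 200,
threshold 0.75 for the single-goal presets; the working-memory criterion
evaluates only the eight hardest trial types, the rank-4 entries nearest
the comparison boundary). Multi-goal schedules advance per goal through a
learning criterion (80% over a trailing 500 choice trials) and then a
random-trial testing block (at least 100 trials, 80% over the trailing
100); an instantly rule-following student therefore advances after exactly
500 + 100 trials per goal. The surrogate persists across goals by default
(`reset_surrogate` to clear it), and `advance_on_budget` supports
fixed-block comparisons. Budget exhaustion is a status flag, not an
exception. Trial budgets default to 20,000 (2AFC), 60,000 (working
memory) and 30,000 per goal (dynamic task); simulations in the tests and
acceptance script use 2,000–3,000-trial runs over 10–20 seeds, sizes chosen
to make the compared effects stable at desk scale.

## Offline analysis

Preprocessing drops habituation-protocol and no-response trials and
concatenates the rest in order; history regressors are then encoded on the
concatenated choice-trial sequence. Windows are 500 trials at a 100-trial
step; a shorter tail is discarded (499 trials → 0 windows, 1000 → 6).

Fitting: cross-validation and significance models minimize the
cross-entropy by full-batch gradient descent (learning rate 0.5, cap 2000
epochs) with early stopping on the held-out fold's loss — stop after 5
consecutive epochs improving by less than 10⁻⁴ — operationalizing "train
until the test loss stabilizes". Fold partitions are seeded disjoint
10-fold splits, fresh per repetition. Window accuracy is the mean held-out
accuracy at the 0.5 probability threshold. Reported window weights come
from the same descent on all 500 trials, stopped when the *training* loss
stabilizes; the mild implicit shrinkage of the unconverged descent keeps
nuisance weights bounded under the WSLS ≡ S1 collinearity, where the exact
MLE (available as `fit_logistic_full`, L-BFGS, cross-checked against
scikit-learn) is noisy. Constant-choice windows are fitted but flagged.

Significance: 10 repetitions × 10 folds give 100 models per window; the
partial model zeroes one regressor's column in the test rows of the trained
full model, and the 100 accuracy differences enter a corrected resampled
t-test — variance of the mean inflated from 1/n to 1/n + n_test/n_train
(50/450 here), df = n − 1, one-sided for "full beats partial". Zero-variance
differences give p = 1. Forcing the correction ratio to 0 recovers the
standard resampled t-test exactly. The 100 significance models are trained
fresh (seeded), separate from the 10 accuracy folds. Regressors are not
standardized: encodings already live in [−1, 1].

Bias indices: performance bias |perf_L/(perf_L + perf_R) − ½| and its
trial-type (presentation count) analogue; both are NaN-flagged when a side
is absent.

Psychophysical kernel: 100 pairs of logistic fits, each on a fresh random
10% subsample of choice trials; one fit on the real 25×40-ms bin
indicators, one on bins shuffled within each trial (temporal structure
destroyed, per-trial event count preserved). Kernel and baseline are the
means of the real and shuffled per-bin weights. Fits use scikit-learn with
C = 10⁴ — effectively unpenalized but finite if a subsample is separable;
subsamples are redrawn if single-class. Fewer than 25 bins is an error.

## Known limitations

- The noise-suppression advantage of the teacher over random selection is a
  transient-phase effect in these simulations: with correct-label
  supervision and the deployed hyperparameters (αλ = 0.01 weight decay),
  both policies flush the initial noise weights within ~100 trials, after
  which trajectories are statistically indistinguishable; long-horizon
  trajectory means therefore dilute the effect. The acceptance script
  reports both the full-run and the first-50-trial statistics.
- The teacher plans one trial ahead with a plain-step learner model; no
  lookahead, no synthetic (off-repertoire) stimuli, no Bayesian weight
  posteriors.
- No inter-trial timing is simulated (trial-granular clock; timestamps
  optional), and no reinforcement-learning students are provided.
- Whether the deployed surrogate resets between goals is unknown; the
  default here is continuous, with a reset flag.
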
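# Methods

## Problem and pipeline

The package detects arrhythmic (anomalous) activity in a univariate
heart-rate series sampled at 0.5 s intervals.  Detection is causal and
window-based: the 15 values preceding step *t* form the input window whose
target is the label at *t*, so a deployed model answers after a single-lag
delay.  Windows are built per series (never spanning series boundaries),
concatenated, and split chronologically — first 70% train, next 10%
validation, final 20% test, floor rounding for train/validation with the
remainder to test — to avoid any temporal leakage.  The test portion is held
behind an access guard that logs every read, so the protocol can assert the
reserved windows are touched only for the one final evaluation per tuning
run (plus the attribution pass of the single best model).

## The classifier

The classifier is a stack of 1–3 Elman recurrent layers,
`a_t = b + W h_{t-1} + U x_t`, `h_t = tanh(a_t)`, consuming the window as a
length-15 sequence of scalars, with one sigmoid output unit reading the top
layer's final hidden state.  A single sigmoid head (rather than a two-unit
softmax) was chosen as the minimal binary formulation.  Inputs are z-scored
with statistics of the training split only.  Training minimizes binary
cross-entropy with Adam (batch size 32, shuffled batches) at the tuned
learning rate, applying inverted dropout to each layer's output stream (the
within-layer recurrent state is kept intact).  Early stopping monitors
validation loss with patience ⌈epochs/3⌉ and the weights of the
best-validation epoch are restored, so the returned model is never worse on
validation than the last epoch trained.  The implementation is plain numpy
with hand-written backpropagation through time; it is deliberately small,
seed-deterministic end to end, and fast enough that a tuning run of dozens
of trainings completes in seconds on one CPU.

## Search space and optimizers

Hyperparameters live in a fixed 7-vector: learning rate [1e-4, 1e-2],
dropout [0.05, 0.2], epochs [30, 60], layer count [1, 3], and three
neuron-count slots [8, 15] (half the window length up to the window length).
Keeping inactive neuron slots in the vector gives every agent the same
dimension regardless of decoded depth; integer dimensions are rounded only
at decode time so velocity semantics stay continuous, and decoding clips
first, making it total over any real 7-vector.

PSO uses the canonical inertia-weight constants: w annealed linearly from
0.9 to 0.4 over the budget, c1 = c2 = 2, velocities clamped to ±10% of each
dimension's range, positions clipped to the box.  GIPSO adds one genetic
step per iteration: the global best is blend-crossed with a uniformly chosen
other agent (per parameter, with probability pc = 0.1 the child takes
α·best + (1−α)·partner with α ~ U(0,1); otherwise it copies the best),
mutated per parameter with probability pm = 0.1 by ± md·rnd (md = 0.1, rnd
uniform over the range width; an alternative halved-magnitude rule
0.5·rnd is available behind `GipsoConfig.halve_mutation`), and the offspring
replaces the particle with the worst current fitness — entering with zero
velocity and an unset personal best, its evaluation deferred to the next
iteration's sweep.  Ties for worst (and best) resolve to the lowest index
for determinism.  Because replacement itself never evaluates, GIPSO spends
exactly pop_size × (T + 1) objective evaluations, the same as PSO.  The GA
baseline is real-coded with tournament selection (k = 2), per-parameter
blend crossover, the same mutation operator, elitism of 1, and the same
evaluation budget.

A behavioural note measured on the bundled benchmarks: at the tiny tuning
budget (population 6, 8 iterations ≈ 54 evaluations) the worst-replacement
step trades exploration for exploitation, which helps on the multimodal
Rastrigin function (median best ≈ 43 vs ≈ 52 for plain PSO over repeated
seeded runs) but can trail plain PSO on the unimodal sphere at that budget;
with a larger budget (population 20, 100 iterations) GIPSO dominates on the
sphere as well.  The package therefore claims median superiority only where
it holds structurally — on the multimodal benchmark — and treats both
optimizers as interchangeable components elsewhere.

## Objective, indicator and metrics

Tuning minimizes the validation error rate (1 − accuracy) and tracks
Cohen's kappa κ = (z_o − z_e)/(1 − z_e) — observed vs chance agreement from
the marginal products — as the indicator, since accuracy alone is
uninformative under the heavy class imbalance typical of this data (≈ 85%
anomalous windows).  Candidates that fail to train are penalized with the
worst fitness 1.0.  All metrics are computed from integer confusion counts
with the anomalous class positive; degenerate denominators raise rather than
silently reporting zero, so broken models surface during tuning.
`reconstruct_confusion` inverts a printed classification report
(per-class precisions, recalls, supports) back to the unique integer matrix
by exhaustive search over the diagonal counts, verifying the printed
precisions reproduce to the printed six-decimal precision — the mechanism
used to tie published report rows, best objective and best indicator
together arithmetically.

## Multi-run statistics

Each optimizer is run repeatedly (default 30) with per-run seeds
base_seed + r over a fixed data split, so run i is paired across
algorithms.  Samples are summarized as best/worst/mean/median/std/var
(sample std, denominator n − 1), screened with Shapiro–Wilk at α = 0.05,
and compared against the control optimizer with the two-sided Wilcoxon
signed-rank test.  The Wilcoxon exact tail (n ≤ 25 effective pairs) is
computed by convolution over doubled midranks — equivalent to enumerating
all 2^n sign assignments and correct under ties — with zero differences
discarded; beyond n = 25 the normal approximation with tie correction is
used.

## Attribution

Per-lag importance uses permutation-sampling Shapley estimation: for each
explained window, features enter in random order and a lag's attribution is
the average output change when it joins the already-present coalition,
absent lags imputed from a background draw (100 training windows by
default).  By construction the per-sample attributions sum to the model
output minus the mean output over the sampled backgrounds, so local
accuracy holds up to Monte-Carlo error that shrinks as the coalition budget
grows; an exact enumeration mode (all 2^D coalitions, Shapley-weighted,
averaged over the full background set) serves as the reference for small D.

## Synthetic data generator

The generator emulates an ambulatory heart-rate recording: an AR(1)
deviation process (coefficient 0.95, innovation sd 2 bpm) around an 85 bpm
baseline, with a Poisson-drawn number (rate 4) of contiguous anomalous
segments whose total extent matches the configured anomalous fraction
(default 0.85, mirroring the heavy imbalance of the motivating test split of
442 normal vs 2454 anomalous windows); anomalous steps carry a +20 bpm mean
shift and +3 bpm extra innovation noise.  Defaults — series length 1800
(15 min at 0.5 s) — were fixed once as plausible resting/arrhythmic values.

What the generator does not emulate: real QRS morphology, measurement
artifacts, gradual onset of arrhythmic episodes, non-stationary baselines,
or anomalies that manifest in variability rather than level.  Passing tests
on this data therefore demonstrate that the pipeline wiring, optimization
and metrics behave correctly and that the classifier can exploit a
level-plus-variance signature; they do not certify clinical detection
performance.  One realistic consequence worth knowing: because anomalous
segments are long and contiguous, a chronological 10% validation slice can
fall entirely inside an anomalous stretch for some generator seeds, leaving
the tuning objective without normal-class signal and degrading the tuned
model's test kappa — the same hazard applies to short real recordings.

## Numerical and protocol choices

- Problem sizes in tests and the reproduction script are scaled to the
  method, not the data: two 1800-step series, population 4, 3 iterations,
  epoch budgets capped at 10, 3 repeats — enough for every behavioural
  property to be exercised while a full study remains a configuration
  change, not a code change.
- The run's best hyperparameters are refit on train+validation before the
  single test evaluation (`refit=False` reuses the tuning-time model).
- Early-stopping improvement is strict (tolerance 1e-12); sigmoid is
  computed via tanh for stability; BCE clips probabilities at 1e-12.
- All randomness flows through numpy Generators seeded explicitly; identical
  configuration and seeds reproduce runs bit-for-bit on one machine.

## Known limitations

- The recurrent cell is a plain Elman unit; gated variants (LSTM/GRU) are
  out of scope.
- Comparator metaheuristics beyond PSO/GA are not implemented; the optimizer
  interface (`objective, space, config, rng → result`) is the plug-in point.
- Attribution is estimated, not exact, at the default budget; the exact mode
  is exponential in the window length and practical only for small windows.
- Headline accuracies from the motivating study depend on an external
  dataset and long stochastic training; this package reproduces their
  arithmetic identities and the method's behaviour at reduced scale instead.
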
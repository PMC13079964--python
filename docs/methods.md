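# Methods

This note records the scientific and numerical choices behind `actisleep`:
what each stage assumes, which knobs matter, what the synthetic data does
and does not emulate, and the known limitations.

## Data model

A record is one participant's series of 1-minute epochs: a non-negative
activity count (missing = NaN, never a sentinel) and an off-wrist flag.
Timestamps are timezone-naive local clock time because every derived
quantity (bedtime, sleep midpoint) is a clock-time concept. Records start
mid-day by convention so that nights span midnight; circular statistics on
a 24-h wheel handle the wrap everywhere a clock time is averaged.

## Epoch sleep/wake scoring

Epochs are scored with the classic one-minute weighted-window rule of Cole,
Kripke et al. (1992): `D = 0.001·(106·A[t−4] + 54·A[t−3] + 58·A[t−2] +
76·A[t−1] + 230·A[t] + 74·A[t+1] + 67·A[t+2])`, sleep when `D < 1.0`. The
threshold and an optional Webster-style wake-extension rescoring pass are
configurable; rescoring is off by default because on the synthetic data it
only amplifies the boundary bias described below.

Because the kernel looks back four epochs, the first ~4 minutes of sleep
after a wake bout and the last ~2 minutes before one are scored wake. Each
wake bout therefore costs roughly 6 minutes of measured sleep. This is a
deterministic property of weighted-window scorers, not noise; recovered
durations run ~6 min low per bout, which is why parameter-recovery
guarantees are stated for consolidated (low-fragmentation) nights.

## Rest-interval detection and night summaries

Actigraphy alone has no diary channel, so the rest interval is detected as
the longest span below an activity threshold — half the record-wide median
of a 21-minute smoothed count series, floored at 5 counts/min — inside an
18:00-to-noon search window per calendar day. Spans shorter than 60 min are
discarded. Within the interval: latency is the time to the first run of ≥ 5
consecutive sleep epochs; the offset is the end of the last sleep run; WASO
counts wake minutes strictly between onset and offset; efficiency is
100·duration/(latency + duration + WASO); the midpoint is the circular
midpoint of onset and offset. A fixed search window necessarily truncates
extremely displaced sleep (e.g. a 10 a.m. onset); see Limitations.

## The two composite scores

**Weekly quality.** The four components are incommensurate (percent and
minutes), so a raw sum cannot produce a bounded 0–12 scale. Each weekly
mean is therefore banded to a 0–3 subscore in the style of the Pittsburgh
Sleep Quality Index and the four subscores are summed. Bands
(configurable): efficiency ≥ 85/75/65 %, latency ≤ 15/30/60 min, duration
≥ 420/360/300 min; WASO has no PSQI analogue, so the package uses
≤ 20/40/60 min. Subscores are monotone by construction: degrading any
single parameter never lowers the score.

**Consistency.** `SleepVar` and `MidpointVar` are standard deviations in
minutes (sample SD for duration; circular SD for midpoint), and
`WeekendDiff` is the absolute circular difference of mean weekday and
weekend midpoints in minutes, combined with weights 0.4/0.3/0.3. Minutes
were chosen over variances (min²) because the published 50/200/400 class
cutoffs are only attainable on a minutes scale for human-range variability;
a variance mode and a duration-based weekend contrast remain selectable.

## Synthetic cohorts

Each night is drawn as bedtime (normal jitter around a habitual bedtime,
plus a weekend shift on day indices 5–6), latency (gamma), duration
(normal, clipped to 1–20 h) and WASO realized as discrete awakening bouts
(Poisson count, Dirichlet lengths) so fragmentation is visible to SD and
zero-fraction features. Counts are negative binomial with variance
m(1 + a·m): daytime mean 250/min, quiet wakefulness in bed 30–80/min, sleep
0.01/min (so most sleep hours have exactly zero counts, as real actigraphy
does — this is what gives the zero-percent feature its signal). All
randomness flows through one seeded generator per participant.

Shipped class profiles were calibrated once so that scoring the noiseless
parameters reproduces the intended class: the three weekly-quality profiles
differ in latency/WASO/duration (e.g. Poor: 80 min latency, 90 min WASO,
280 min sleep), the four consistency profiles in duration SD, midpoint SD
and weekend shift. Because a 7-night sample of an extreme profile
occasionally lands outside its class band, `generate_cohort` can redraw a
participant deterministically until the ground-truth class matches the
request; cohort labels are exact by construction.

What the simulation does **not** emulate: naps, gradual wake-sleep
transitions, device-specific count scalings, light or heart-rate channels,
and population heterogeneity beyond the per-class profile. Passing tests
show the pipeline recovers structure it was designed to see; they do not
certify clinical performance on real cohorts.

## LSTM feature extractor

Stacked LSTM (75-50-25-15 units for the weekly metric, 100-80-60-40 for
consistency), tanh cell nonlinearity, inverted dropout 0.2 on layer inputs,
softmax head on the last layer's final-time-step output, cross-entropy
loss, Adam (1e-3, batch 32), up to 100 epochs with early stopping on a 10 %
validation split (patience 25). The head supervises training; downstream
stages use the 15- or 40-dimensional recurrent output as features.
Implemented in numpy (float64, full BPTT) and verified against central
finite differences.

Numerical choices that mattered: recurrent weights are initialized
orthogonally (per gate) — with plain Glorot recurrence the 4-layer stack
sits at the uniform-prediction plateau for well over 100 epochs on
cohort-sized data, while orthogonal initialization trains within the
default budget. Gradients are clipped element-wise at ±5. Training is
bit-reproducible for a fixed seed.

## Feature selection

Wrapper fitness is mean stratified k-fold CV accuracy (default 5 folds) of
a small classifier on the masked columns; when participant groups are
supplied the folds are additionally grouped, because window-level fitness
leaks participant identity and then selection optimizes the wrong
objective (empirically, grouped fitness is what makes selection beat the
no-selection baseline on held-out grouped evaluation). An empty mask
scores 0 (penalty); ties break toward smaller subsets. Fitness values are
memoized by mask, so revisited subsets are free.

The genetic search uses tournament selection (size 2), single-point
crossover (0.6), per-bit mutation (0.033), elitism 1, population 20, 20
generations, linear-SVM fitness. The PSO is the geometric, velocity-free
binary variant: every bit of a particle's next position is copied from its
current position, personal best, or global best with probabilities
0.33/0.34/0.33, then mutated per-bit with probability 1/n; logistic
regression computes its fitness. The published velocity-update equation is
documented as motivation only — the prose variant (no velocity, with
mutation) is what is implemented. The final subset is the bitwise union of
the two searches' masks. Selection operates on the deep block only; the
three statistical features are always appended afterwards.

## Classification and evaluation

Linear SVM, C = 0.1, one-vs-rest decision shape. Cross-validation is
stratified and grouped by participant (all of a participant's windows share
a fold); fold counts shrink with a logged warning when the smallest class
has fewer groups than requested folds. Metrics come from pooled held-out
predictions: accuracy, precision/recall/F1 macro and weighted, one-vs-rest
macro AUC computed per class from decision scores (invariant to monotone
score transforms), and the confusion matrix. Participant-level predictions
are majority votes over a participant's windows with ties resolved to the
worst class (conservative). Ablation variants toggle exactly one
component: end-to-end LSTM classification (retrained inside each fold), no
metaheuristic selection, no statistical features, or tree ensembles
(100 trees) on the same fused features.

## Permutation importance

Importance of a feature is the baseline held-out accuracy minus the mean
accuracy after shuffling that column (10 seeded repeats). It is measured on
CV test folds, never on training data, because train-set importance is
biased toward overfit features. Importances may be negative and do not sum
to anything meaningful; ties in the ranking break lexicographically.

## Problem sizes

Study-scale defaults follow the cohort design the method was published
with: 28 participants (10/10/8) for the weekly metric, 40 (10 × 4) for
consistency, 7 days each, giving 13 windows per participant. The ablation
and selection studies in the acceptance script use 12-participant cohorts
and a 40-epoch extractor schedule — sizes chosen so a complete replication
runs in minutes on a single CPU while preserving every qualitative
contrast; the full-schedule pipeline is what the demo cohort runs.

## Known limitations

* The 18:00–noon rest search window truncates severely displaced sleep, so
  scored consistency scores attenuate (~0.8×) for the most irregular
  profiles and scored-class agreement for the Very Poor consistency class
  falls below the ≥ 90 % seen elsewhere; classification experiments use
  generator labels and are unaffected.
* Weighted-window epoch scoring has an inherent ~6-min-per-bout duration
  bias (see above); duration-recovery guarantees hold for consolidated
  nights.
* The weekly composite's subscore bands are an interpretation — the
  composite's components have no published quantization — and all cutoffs
  are exposed in the configuration for sensitivity analysis.
* The LSTM is trained once on all windows before the SVM's grouped CV
  (matching the published sequential design); deep features are therefore
  not leakage-free with respect to the CV, while the selection and SVM
  stages are. The `pure_lstm` variant, retrained per fold, provides the
  leakage-free reference point.
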
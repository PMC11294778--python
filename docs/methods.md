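# Methods

## Task and data model

The unit of prediction is an *instance*: a reference date on which a
patient actually had an HbA1c test, the N-year history of HbA1c values
before (and including) that date, and a binary outcome — whether any
measurement in the 365 days after the reference date is at or above 8.0%
(the boundary counts as poor control). A patient contributes one instance
per in-year test date; instances whose one-year outcome horizon extends
past the last recorded date are dropped, as are (theoretical) instances
with no observed input slot.

History windows use 365-day years, consistent with the grid width
`W = ceil(N·365/7)` (53 slots for N=1, 261 for N=5). Measurements are
quantized to Monday–Sunday weeks: multiple values in one week are
averaged, empty weeks stay missing. No interpolation, normalization,
outlier handling, or dimensionality reduction is applied; missingness is
carried as an explicit boolean mask (NaN in files) and handled by the
attention mask alone. Slot W−1 is the week containing the reference date,
and the reference-date measurement itself is part of the input (the
alternative is available via `include_reference_week=False`); this
guarantees every instance has at least one observed slot.

## Architecture

Pre-norm transformer. Observed values are embedded as
`value · w + b + pos(week)` with a non-learned sinusoidal position code,
so the parameter count is independent of W and one model accepts N=1..5
inputs. Missing weeks get exactly-zero embedding rows; combined with
zero attention weight on missing keys, this makes the model's output
bit-invariant to whatever sentinel is stored at a missing slot (tested
end to end).

Encoder self-attention is restricted to observed keys at or before the
query week (key-padding plus causal masking); softmax rows are computed
over the valid set only, with exact zeros elsewhere, and a row with no
valid key yields an all-zero weight row rather than NaN (such query
positions are themselves missing and are never read downstream). The
decoder is a single learned classification query token that cross-attends
over encoder states through each decoder layer (cross-attention + feed
forward; with one token, decoder self-attention would be an identity-like
no-op and is omitted). A final linear layer and sigmoid produce the
probability of poor control. A separate linear regression head over
encoder states serves the self-supervised task. All computation is numpy
with hand-written backpropagation; the test suite verifies every gradient
path against central differences at float64.

## Training protocol

1. **Self-supervised pretraining** (encoder + regression head): at every
   observed week that has a later observed week, predict the *next
   observed* value; minimize mean squared error over exactly those
   positions. (The alternative reading — predict week t+1 only when it is
   observed — is available as `ssl_target="next_week"`.) The SSL loss is
   plain MSE: a focal-style loss is specific to classification, and the
   pretraining task is a regression.
2. **Supervised training** (decoder): focal loss
   `−α(1−p_t)^γ ln p_t` with a constant α multiplier (γ=2.0, α=0.25
   defaults, both configurable; probabilities clamped to ±1e-7).
   The encoder is frozen by default — self-attention weights belong to the
   self-supervised stage, cross-attention weights to the supervised stage —
   which also lets encoder states be computed once and reused every
   iteration. `freeze_encoder=False` enables joint fine-tuning.
3. **Threshold selection**: exhaustive scan of all distinct training
   scores plus {0, 1} for the threshold maximizing F1 (decision rule
   `score ≥ threshold`); ties break toward the higher threshold (fewer
   predicted positives).

Both stages run a fixed iteration budget with no early stopping, uniform
minibatch sampling with replacement, and Adam. The full-scale defaults are
learning rate 1e-4, batch 512, 20,000 iterations per stage. The desk
profile (2+2 layers, hidden 64, feed-forward 256, batch 64, 2,000
iterations) raises the learning rate to 1e-3: its training budget is ~80×
smaller, and at 1e-4 the scaled-down run stops far short of convergence —
on a synthetic benchmark where a gradient-boosted comparator reaches
held-out ROC-AUC 0.97, the underconverged model stalls near 0.87, while at
1e-3 both stages converge and the model matches the comparator.
All randomness — initialization,
batch order, dropout — derives from a single seed; inference is
deterministic (dropout off, default rate 0).

## Evaluation

Rolling-origin: train on instances referenced in year y−1, test on year y,
sliding y across the requested range; years with single-class test sets
are skipped with a warning. Metrics are ROC-AUC (Mann–Whitney: ties count
half), PR-AUC (step-wise interpolation over distinct thresholds — linear
interpolation of PR curves is optimistically biased and is not used),
accuracy and F1 at the selected threshold, each with percentile bootstrap
95% CIs (record-level resampling, 1000 replicates by default, seeded;
single-class resamples are redrawn and the interval is refused if more
than half the replicates fail). Pooled results concatenate per-year scores
and decisions; per-year means are also reported, since a pooling rule is
not canonical.

Leakage audit: for every split it is asserted that the latest training
reference date precedes the earliest test outcome window, i.e. every
training *input* precedes every test outcome. Note that with adjacent
train/test years the training *outcome* windows necessarily reach into the
calendar year where test outcomes begin; that overlap involves no flow of
test information into training inputs and is inherent to the
adjacent-year rolling design.

The comparator is LightGBM consuming the same weekly grid as equally
spaced features with NaN missing values routed natively (its standard
missing-data handling). It is an external dependency, deliberately not
reimplemented, and it also anchors the concordance groups of the
interpretability analysis (true positives in both models, true negatives
in both, and the two disagreement groups on true positives).

## Interpretability reductions

Attention maps are aggregated by averaging heads within a layer, then
averaging layers (the plotted curves of attention-weight analyses rarely
state a reduction; this is the symmetric default, and the raw per-layer,
per-head maps are retained on every record). The per-week self-attention
salience of key week s is the mean weight it receives across observed
query rows. Cross-attention aggregates to a probability vector over
observed weeks (sums to 1, exact zeros at missing weeks). Group profiles
average level, salience, and cross-attention per week over the instances
in which that week is observed; the week axis is reported as weeks before
the reference date.

## Synthetic cohort generator

The generator emulates the marginal statistics of a specialist outpatient
HbA1c stream; it is the package's stand-in for protected hospital data and
is labelled synthetic throughout.

Per patient: a stable level `mu_i ~ N(7.05, sigma_between)` (the 7.05
default is `hba1c_mean 7.1` plus a −0.05 `mean_offset`, the dial that
steers instance-level outcome prevalence into the observed 27–32% band);
a linear drift with slope SD 0.05 %/year (slow on-treatment progression —
larger drifts inflate the 10-year marginal variance far beyond the 1.1%
target); a shared seasonal cosine with amplitude 0.15% peaking at
day-of-year 45 (winter peak; within the 0.1–0.4% range reported for
seasonal HbA1c variation); a weekly AR(1) deviation with coefficient 0.9
and innovation SD 0.12% (HbA1c integrates 1–2 months of glycemia, hence
strong week-to-week persistence); and measurement noise SD 0.12%
(laboratory CV of a few percent at these levels). `sigma_between` is
derived so the marginal SD of observed values matches the configured
`hba1c_sd` (1.1%) after subtracting the stationary AR variance and the
noise variance. Setting `ar_coefficient=0` switches off within-patient
dynamics entirely (a static patient apart from drift and noise), which is
the documented degenerate contract of the generator.

Visit dates follow a gamma renewal process with mean gap
`52.18/visits_per_year_mean` weeks and shape `mean/sd²` of the yearly
count target (≈0.98 at the 7.7/2.8 defaults, i.e. near-exponential gaps —
which by itself reproduces the observed count SD). Visits are rounded to
calendar days, at most one per patient-day; multiple visits in one week
exercise within-week averaging. Values are clipped to (0.05, 19.95) and
rounded to 4 decimals.

What the generator does *not* emulate: treatment-intensification feedback
(real poor-control trajectories bend because physicians react), visit
scheduling that depends on disease severity (sicker patients are tested
more often), demographic structure, assay drift across years, and
patient entry/exit (every synthetic patient spans the whole study window).
Passing tests on this cohort therefore demonstrate that the pipeline
recovers a recent-history-driven outcome signal under realistic sparsity
and seasonality — not that the clinical performance figures transfer.

## Problem sizes and numerical choices

The scaled-down benchmark used by the test suite and the acceptance script
is a 500-patient cohort over 2012–2015 (~3,800 training instances
referenced in 2013, ~3,800 test instances in 2014, prevalence ≈ 0.33),
with the desk model profile; one full run takes a few minutes on one CPU.
Weights are float32 (gradient checks run at float64); attention softmax
subtracts the row maximum; layer-norm epsilon is 1e-5; Adam uses the
standard bias correction with β=(0.9, 0.999). Parameter initialization is
N(0, 0.02); the classification query token is learned. Model checkpoints
are a single `.npz` with a JSON metadata header (configuration, threshold,
and training flags) alongside the weight arrays.

## Known limitations

- The full-scale configuration (batch 512, 20,000 iterations) is the
  faithful default but is not exercised end-to-end by the test suite; the
  desk profile is.
- The focal loss uses a constant α for both classes (the formula as
  specified for this model), not the class-conditional α_t variant common
  elsewhere; with γ=0, α rescales cross-entropy uniformly.
- Attention weights are a model-internal quantity; the recency analysis
  here shows where the trained model allocates attention, which is not a
  causal attribution.
- The no-leakage audit asserts input/outcome ordering, not patient
  disjointness: as in the underlying design, a patient may appear in both
  training and test years (patient identity is not a model input).
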
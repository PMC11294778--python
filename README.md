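# glycontrol

Predicting poor glycemic control from irregular HbA1c time series with an
interpretable attention model.

## The problem

Hemoglobin A1c (HbA1c) reflects average blood glucose over the preceding
1–2 months and is the standard monitoring test in type 2 diabetes. A value
of 8% or more signals poor glycemic control and usually triggers more
intensive intervention. Physicians would like an early warning: given a
patient's HbA1c history under usual care, will control be poor at any
point in the next year? The difficulty is that outpatient laboratory
series are irregularly spaced — a typical specialist-clinic patient is
tested about 7.7 times a year, so a weekly grid over one year is ~85%
empty — and levels fluctuate seasonally.

`glycontrol` is a toolkit for this prediction task. It contains:

- a transformer classifier (`HbA1cTransformer`, scikit-learn estimator
  API) whose attention mask skips missing weeks *exactly* instead of
  imputing them, with causal masking so no position sees the future;
- preprocessing that quantizes irregular measurements onto Monday–Sunday
  weekly grids (within-week averaging, no interpolation or normalization)
  and builds labeled instances anchored at real test dates;
- a two-stage training protocol: self-supervised next-value pretraining of
  the encoder, then supervised focal-loss training of a cross-attention
  decoder, then F1-maximizing threshold selection on training data;
- attention-based interpretability: per-instance self-/cross-attention
  weights and group-averaged attention profiles, including concordance
  groups against a LightGBM comparator;
- rolling-origin temporal evaluation (train on year *y−1* references, test
  on year *y*) with ROC-AUC, PR-AUC, accuracy and F1 plus bootstrap 95% CIs;
- a seeded synthetic cohort generator emulating the specialist-clinic data
  regime (7.7 tests/patient-year, HbA1c 7.1% ± 1.1%, seasonal fluctuation,
  ~27–32% instance-level prevalence of poor control), so the whole pipeline
  runs without access to protected clinical data.

## The model

An instance is a weekly grid `x_1..x_W` (W = ⌈N·365/7⌉, so 53 for one
year) with an observation mask `m`. Observed values are embedded by a
linear projection plus a sinusoidal position code; missing weeks get
exactly-zero rows. The encoder applies masked multi-head self-attention:
query week *t* attends to key week *s* with weight

    A_ts = softmax_s( q_t·k_s / √d_h )   restricted to { s ≤ t, m_s = 1 },

with weight exactly 0 on missing or future weeks. A single learned
classification query cross-attends over encoder states through the decoder
layers; a linear layer and sigmoid give P(poor control within 1 year).
The label is positive iff any measurement in the 365 days after the
reference date is ≥ 8.0%.

Pretraining minimizes squared error of a next-observed-value regression
head at observed positions only; supervised training minimizes focal loss
`−α(1−p_t)^γ ln p_t` (γ=2, α=0.25 by default) with the encoder frozen.
The default configuration is 4 encoder + 4 decoder layers, 4 heads, hidden
128, feed-forward 512, Adam 1e-4, batch 512, 20,000 iterations per stage
with no early stopping; `HbA1cTransformer.desk()` is a scaled-down profile
(2+2 layers, hidden 64, batch 64, 2,000 iterations) for laptop-scale runs.
Everything is implemented in numpy with hand-written backpropagation,
verified by central-difference gradient checks in the test suite.

## Worked example

```python
from datetime import date
import glycontrol as g

cohort = g.generate_cohort(g.CohortConfig(
    n_patients=500, start_date=date(2012, 1, 1), end_date=date(2015, 12, 31), seed=7))

train = g.build_instances(cohort, 2013)   # one instance per 2013 test date
test  = g.build_instances(cohort, 2014)
Xtr, ytr = g.instances_to_xy(train)       # (n, 53) grids, NaN = missing week
Xte, yte = g.instances_to_xy(test)

est = g.HbA1cTransformer.desk(random_state=1).fit(Xtr, ytr)
scores = est.predict_proba(Xte)[:, 1]
print(f"ROC-AUC {g.roc_auc(scores, yte):.3f}  threshold {est.threshold_.value:.3f}")
```

prints

```
ROC-AUC 0.977  threshold 0.558
```

meaning the scaled-down model, trained only on 2013-referenced instances,
ranks a random truly-poor-control 2014 instance above a random good-control
one 97.7% of the time; 0.558 is the decision threshold that maximized F1 on
the training scores. Attention explanations for any instance come from
`est.attention_records(Xte)`: on this benchmark the cross-attention places
about 0.42 of its mass on the most recent quarter of observed weeks versus
about 0.15 on the oldest quarter — the model leans on recent HbA1c.

The same pipeline is available from the shell:

```bash
glycontrol simulate --out cohort.csv --seed 17
glycontrol preprocess --in cohort.csv --year 2013 --out train.csv
glycontrol train --train train.csv --profile desk --seed 7 --out model.npz
glycontrol evaluate --model model.npz --test test.csv --out report.json
glycontrol explain --model model.npz --test test.csv --train train.csv --out profiles/
```

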
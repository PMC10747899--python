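# gipso

Swarm-tuned recurrent anomaly detection for heart-rate time series.

Arrhythmic (anomalous) heartbeat activity can be detected from a univariate
heart-rate signal (beats per minute, sampled every 0.5 s) by a lightweight
Elman recurrent network that classifies each time step from the 15 preceding
values.  How well such a network performs depends strongly on its
hyperparameters — learning rate, dropout, epoch budget, depth and width —
and this package tunes them with a **genetically inspired particle swarm
optimizer (GIPSO)**: classic inertia-weight PSO augmented, once per
iteration, with blend crossover of the global best against a random agent,
per-parameter mutation, and replacement of the worst particle by the
offspring (whose evaluation is deferred, so the evaluation budget equals
plain PSO's).

It is intended for researchers benchmarking metaheuristic hyperparameter
tuners on physiological time-series classification, and ships everything
that workflow needs:

- `gipso.metaheuristics` — PSO, GIPSO and a real-coded GA baseline, plus
  sphere/Rastrigin benchmarks for oracle testing;
- `gipso.search_space` — the 7-dimensional mixed continuous/integer
  hyperparameter box and its decoding;
- `gipso.recurrent_classifier` — a seed-deterministic numpy Elman RNN
  (BPTT + Adam, early stopping at patience = ⌈epochs/3⌉);
- `gipso.data` — CSV I/O, a synthetic labeled heart-rate generator (AR(1)
  baseline with contiguous anomalous segments), lag windowing and
  chronological 70/10/20 splits;
- `gipso.evaluation` — confusion-matrix arithmetic: precision/recall/F1,
  accuracy, the error-rate objective, Cohen's kappa indicator, ROC/PR
  points, and reconstruction of integer confusion matrices from printed
  classification reports;
- `gipso.study_stats` — the 30-run protocol: summary tables, Shapiro–Wilk
  screening, exact Wilcoxon signed-rank comparison;
- `gipso.interpretation` — Shapley-style per-lag attribution;
- `gipso.orchestration` + a `gipso` CLI — the end-to-end experiment driver.

## The model and the objective

Each recurrent layer follows the Elman recurrence
`a_t = b + W h_{t-1} + U x_t`, `h_t = tanh(a_t)`, with a single sigmoid
output unit reading the final hidden state; the positive class is anomalous
activity.  The optimizer moves agents by

```
v ← w·v + c1·r1·(p_i − x) + c2·r2·(p_g − x),   x ← x + v,
```

with `w` annealed linearly from 0.9 to 0.4, `c1 = c2 = 2`, velocities
clamped to 10% of each dimension's range, and minimizes the validation
**error rate** `1 − accuracy`, tracking **Cohen's kappa**
`κ = (z_o − z_e)/(1 − z_e)` as the imbalance-robust indicator.  The GIPSO
genetic step blends child parameters `c_j = α·a_j + (1−α)·b_j` with
per-parameter probability `pc = 0.1` and mutates parameters by `± md·rnd`
(`md = 0.1`, `rnd` uniform over the dimension's range).

## Worked example

Reconstruct the integer confusion matrix behind a published per-class
report row (precisions 0.948357/0.984615, recalls 0.914027/0.991035,
supports 442/2454) and recompute every aggregate from it:

```python
from gipso import classification_report, cohen_kappa, error_rate, reconstruct_confusion

cm = reconstruct_confusion((0.948357, 0.984615), (0.914027, 0.991035), (442, 2454))
rep = classification_report(cm)
print((cm.tn, cm.fp, cm.fn, cm.tp))   # (404, 38, 22, 2432)
print(f"{rep.accuracy:.6f}")          # 0.979282
print(f"{error_rate(cm):.6f}")        # 0.020718  (the tuning objective)
print(f"{cohen_kappa(cm):.6f}")       # 0.918695  (the indicator)
print(f"{rep.macro_f1:.6f}")          # 0.959345
```

The accuracy, error rate and kappa printed above are exactly the figures a
consistent report/objective/indicator triple must share: the error rate is
one minus the accuracy, and kappa discounts the 74.5% agreement expected
from the heavily imbalanced marginals (442 normal vs 2454 anomalous
windows).

Run a small tuning study on synthetic data from the command line:

```
gipso tune --config examples/experiment.yaml
```

which prints (numbers from this exact config and seed):

```
gipso: best objective 0.019608, median 0.044818 over 3 runs
pso: best objective 0.049020, median 0.050420 over 3 runs
artifacts written to results/demo
```

i.e. the best GIPSO-tuned network misclassifies 1.96% of the 714 held-out
test windows, and per-run traces, summary/report/hyperparameter tables,
Shapiro–Wilk and Wilcoxon p-values and the per-lag attribution summary land
in `results/demo/` as CSV.

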
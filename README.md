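# swarmbalance

Swarm-optimized SMOTE rebalancing for imbalanced binary classification,
with a windowed adaptive variant for large datasets.

## The problem

Clinical and screening datasets are usually lopsided: patients among healthy
controls, active compounds among inert ones, at ratios from 2:1 to beyond
950:1. A classifier trained on such data can post 99% accuracy by voting for
the majority class while being useless on the cases that matter. Cohen's
kappa exposes the trick — it corrects agreement for chance:

```
kappa = (Po − Pc) / (1 − Pc)
Po = (TP + TN) / (P + N)
Pc = [(TP+FP)(TP+FN) + (FN+TN)(FP+TN)] / (P+N)²
```

A majority-vote classifier scores kappa = 0 no matter how high its accuracy.
The conventional credibility bands are kappa ≥ 0.75 (high), 0.4 ≤ kappa <
0.75 (moderate), and kappa < 0.4 (low or none).

SMOTE rebalances the data by synthesizing minority samples on segments
between a minority point `x_i` and one of its `K` nearest minority
neighbors `x_t`:

```
x_new = x_i + u · (x_t − x_i),   u ~ Uniform[0, 1]
```

Its two parameters — the oversampling percentage `S` (S = 100 doubles the
minority class) and the neighbor count `K` — strongly influence the result,
and good values are dataset-specific. `swarmbalance` searches (S, K) with a
particle swarm (PSO) or bat algorithm (BA), judging each candidate by
SMOTE + k-fold cross-validated classification and accepting a candidate over
the incumbent only if

- both are credible (kappa > T, default T = 0.4) and the candidate is more
  accurate, **or**
- the candidate is credible and the incumbent is not.

For large datasets a whole-table search is slow and often fruitless. The
adaptive variant treats the table as a stream cut into N windows with
lengths in 1:2:…:N proportion (N = 3 by default), searches windows 1..N−1
with each search warm-started at the previous window's optimum, evaluates
the final window under the propagated parameters without searching, and
reports the mean of the per-window accuracies and kappas.

## Worked example

Generate a separable 500-vs-25 screening table (ratio 20:1), look at the raw
classifier, then let the swarm pick (S, K):

```
$ swarmbalance simulate --majority 500 --minority 25 --features 5 \
      --separation 4 --seed 7 --out screen.csv
wrote 525 rows (25 positive / 500 negative, ratio 20.0000) to screen.csv

$ swarmbalance evaluate --input screen.csv -S 0 -K 5 --folds 3 --seed 7
...  "Accuracy": 0.9523809523809523,  "Kappa": 0.0,  "band": "low"  ...

$ swarmbalance balance --input screen.csv --algorithm pso --smoke \
      --folds 3 --seed 7
...
  "best": { "S": 263, "K": 23 },
  "credible": true,
  "band": "high",
  "Psize": 90, "Nsize": 500,
  "result": { "Accuracy": 1.0, "Kappa": 1.0, ... },
  "evaluations": 55, "unique_evaluations": 51
...
```

Untreated, the network votes majority: 95.2% accuracy, kappa 0.0 — a result
with no credibility. The swarm finds S = 263, K = 23, growing the minority
from 25 to Psize = 90 (25 + ⌊25·263/100⌋), after which the cross-validated
classifier separates the classes perfectly (kappa 1.0, band "high"). Note
the balance need not be complete: 90 vs 500 already suffices here.
`--smoke` uses a desk-scale swarm (population 5, 10 iterations); drop it for
the full population-20 × 1000-iteration search. The same pipeline is
available in Python via `swarmbalance.swarm_balance` /
`swarmbalance.adaptive_balance`.

`swarmbalance adaptive --input big.csv --windows 3 ...` runs the windowed
variant; `swarmbalance bruteforce --dry-run ...` prints the exhaustive grid
size a sweep would need (186,219 points for S ∈ [100, 9900], K ∈ [2, 20]).

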
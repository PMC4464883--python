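# boostsel

Stability selection with per-family error-rate (PFER) control on top of
component-wise gradient boosting.

Boosting with early stopping selects variables, but tends to keep too many
noise variables. `boostsel` wraps it in stability selection: the data are
repeatedly split in half (complementary pairs by default), each half is
boosted *until q distinct base-learners have been selected*, and
base-learners whose relative selection frequency reaches a threshold
`pi_thr` form the stable set. The expected number of falsely selected
variables is bounded above, under three successively tighter assumptions:

* **none** — worst case, `q^2 / ((2*pi_thr - 1) * p)`;
* **unimodal** — unimodal simultaneous selection probabilities;
* **r_concave** — r-concave simultaneous (r = -1/2) and marginal
  (r = -1/4) selection probabilities, evaluated by numeric maximization of
  the tail probability over extremal r-concave distributions.

Given any two of `(q, pi_thr, PFER_max)` the third is resolved from the
bound, on the frequency grid of multiples of `1/(2B)`.

## Contents

| module                 | what it does |
|------------------------|--------------|
| `boostsel.losses`      | Gaussian / binomial losses, negative gradients |
| `boostsel.learners`    | linear, P-spline and ridge/categorical base-learners; degrees-of-freedom resolution |
| `boostsel.boosting`    | component-wise boosting (`boost`, `boost_until_q`, `cv_mstop`) |
| `boostsel.bounds`      | the PFER calculus (`pfer_bound`, `d_value`, `solve_cutoff`, `solve_q`, `pcer_equivalent`) |
| `boostsel.stability`   | subsampling schemes, selection frequencies, stable sets, stability paths, `stabsel`, `rethreshold` |
| `boostsel.simulation`  | benchmark generators (linear logistic, Gaussian additive), TPR/FP metrics, experiment harness |
| `boostsel.casestudy`   | log-linear amino-acid interaction pipeline for phenotype-microarray data, plus a synthetic fixture generator |
| `boostsel.cli`         | the `boostsel` command |

## Library quick start

```python
import numpy as np
from boostsel import linear, stabsel, SubsampleScheme

rng = np.random.default_rng(1)
X = rng.standard_normal((100, 50))
y = 2 * X[:, 0] - X[:, 1] + rng.standard_normal(100)

result = stabsel(
    X, y, "gaussian", [linear(j) for j in range(50)],
    q=5, pfer_max=1.0, assumption="r_concave",
    scheme=SubsampleScheme("complementary_pairs", B=50, seed=7),
)
print(result.pi_thr, result.stable)
```

## Command line

```sh
# resolve the (q, cutoff, PFER) triangle
boostsel params --p 57 --q 10 --pfer 1 --B 50 --assumption unimodal

# stability selection on a CSV (response column "y")
boostsel stabsel --data data.csv --response y --family gaussian \
    --q 5 --pfer 1 --assumption r_concave --seed 1 --out result.json

# change the error bound without re-running the subsampling
boostsel rethreshold --result result.json --pfer 2 --assumption unimodal

# benchmark scenarios and simulation grids
boostsel simulate --family gaussian_additive --n 500 --p 50 --p-infl 3 \
    --seed 1 --out sim.csv
boostsel experiment --config grid.yaml --out results.csv

# synthetic phenotype-microarray fixture and the two-stage case study
boostsel fixture --seed 1 --shift Tyr=0.3 --out pm.csv
boostsel casestudy --data pm.csv --q 10 --pfer 1 --assumption unimodal \
    --seed 1 --out case.json
```

An `experiment` config is YAML:

```yaml
reps: 10
master_seed: 1
B: 50
scenarios:
  - {family: logistic_linear, n: 100, p: 100, p_infl: 3}
params:
  - {q: 8, pfer_max: 1.0, assumption: none}
  - {q: 8, pfer_max: 1.0, assumption: r_concave}
```

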
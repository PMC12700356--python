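# dcglearn

Causal discovery on **directed cyclic graphs** from longitudinal panel data.

The package implements a linear non-Gaussian structural model that couples
time-lagged effects with possibly *cyclic* instantaneous effects:

```
Y_j = mu + sum_{l=0..Ly} B_l Y_{j-l} + sum_{l=0..Lx} A_l X_{j-l} + E_j
```

with a stable (spectral radius < 1), zero-diagonal instantaneous matrix
`B0` and independent Laplace errors.  It provides:

- **`dcglearn.graphs`** — weighted digraph algebra: simple-cycle
  enumeration, stability checks, equilibrium solves, and conversions
  between coefficient matrices and unmixing matrices `W = I - B`.
- **`dcglearn.equivalence`** — the ICA equivalence class made executable:
  admissible row-permutations, irreducible decomposition, cycle-reversal
  graph surgery, exhaustive class enumeration, and identifiability
  certificates from declared instrumental variables.
- **`dcglearn.simulate`** — panel simulators with Laplace scale-mixture
  errors and two turnkey benchmark scenarios (a four-outcome graph with
  joint cycles and a single instrument; a three-outcome graph with lag-1
  dynamics and covariates, effect size scaled by `eta`).
- **`dcglearn.infer`** — fully Bayesian structural learning: spike-and-slab
  priors on every coefficient, normal scale-mixture data augmentation,
  Metropolis-within-Gibbs updates for the instantaneous entries (the
  `log|det(I - B0)|` Jacobian is handled exactly and stability is enforced
  by rejection), median-probability-model edge selection, coefficient-decay
  lag selection, a constrained-hierarchy prior variant, and post-hoc
  identifiability validation of the learned graph.
- **`dcglearn.pipeline_io`** — long-format CSV panel I/O, replicated
  simulate-fit-select experiment drivers, and DOT/CSV/JSON reports.

## Tests

```bash
python -m pytest -q tests/
```

The suite includes `tests/test_acceptance.py`, which checks the worked
matrix examples exactly and re-runs the simulation benchmarks at reduced
replication (30 replicates, 1,500 MCMC iterations) with binomial
tolerances.  The full suite takes roughly 10–20 minutes on one CPU; the
non-acceptance portion runs in about two minutes
(`pytest -q tests/ --ignore tests/test_acceptance.py`).

## CLI

```bash
dcglearn simulate --scenario 1 --n 1000 --instrument covariate --seed 7 --out panel.csv
dcglearn fit --data panel.csv --ly 0 --lx 0 --iters 5000 --burnin 2500 --thin 5 --seed 7 --out results/
dcglearn select-lags --data panel.csv --lmax 3 --seed 7
dcglearn identify --graph learned.json --instruments iv.json
dcglearn enumerate --graph learned.json --stable-only
dcglearn replicate --scenario 1 --n 1000 --replicates 10 --seed 7 --out report/
```

`identify` expects a JSON graph (`{"weights": [[...]], "labels": [...]}`,
target-row convention: entry `(q, p)` is the edge `p -> q`) and a JSON map
from outcome index to instrument name.

## Conventions

- Coefficient matrices use the **target-row convention**: `weights[q, p]`
  is the coefficient of the edge `p -> q`.
- An edge exists when its coefficient magnitude exceeds the zero tolerance
  (default `1e-8`).
- A graph/SCM is *stable* when the spectral radius of `B0` is strictly
  below 1; boundary cases classify as unstable.
- Row-permutations act on unmixing matrices as "row `r` moves to row
  `phi(r)`"; a permutation is *admissible* when the permuted matrix has a
  nonzero diagonal.
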
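# wassreg

Wasserstein-distance matrix regression: joint multi-task score prediction and
whole-feature selection where *both* the empirical loss and the row-sparsity
regularizer are entropy-smoothed, KL-relaxed optimal-transport costs.

## Who this is for

Researchers relating a table of nonnegative imaging markers (e.g. regional
gray-matter density or volumetric measures, one row per marker, one column
per subject) to a handful of cognitive assessment scores, who want (a)
predictions of the score profile and (b) a ranking of the markers that drive
it. Classical approaches measure the residual and the weights with matrix
norms (Frobenius, l2,1, nuclear), which ignore the geometry of score space.
Here both terms are transport costs, so moving predicted mass between nearby
score tasks is cheap and between distant ones expensive.

## The model

With features **A** ∈ R^{m×l}, scores **Y** ∈ R^{l×n} and nonnegative weights
**Z** ∈ R^{m×n}:

    min_{Z ≥ 0}  Σ_{i=1..l} f_{(AᵀZ)^i, Y^i}(P^(i))  +  λ Σ_{j=1..m} f_{Z^j, t}(P̂^(j))

    f_{a,b}(P) = γ KL(P|K) + μ KL(P·1|a) + μ KL(Pᵀ·1|b),     K = exp(−C/γ)

where KL is the generalized Kullback–Leibler divergence, C a normalized
ground cost over the n score tasks, and t a (near-)zero target measure: the
regularizer transports each feature's weight row toward zero mass, so
uninformative features are emptied entirely — transport-driven feature
selection. The relaxed marginals (weight μ) let raw rows of unequal mass be
compared directly, with no histogram preprocessing.

The solver is block coordinate descent: all transport plans are updated by
batched generalized Sinkhorn scaling (exponent μ/(μ+γ)), the weight matrix by
monotone accelerated projected gradient; the objective is non-increasing
across sweeps. Ridge and l2,1-norm selectors are included as baselines, and a
nested five-fold cross-validation harness reproduces the standard
select-top-k-then-ridge-predict RMSE protocol. See `docs/methods.md` for the
full account.

## Worked example

```python
import numpy as np
from wassreg import WassersteinMatrixRegression, generate, support_recovery

# synthetic cohort: 30 markers, 80 subjects, 3 scores, 4 truly active markers
inst = generate(m=30, l=80, n=3, s=4, noise_sd=0.05, seed=11)
res = WassersteinMatrixRegression(inst.A, inst.Y).fit(lam=1.0)
print(res.summary(top=6))
```

prints

```
Wasserstein Matrix Regression Results
=====================================================
features (m):     30    samples (l):     80    tasks (n):    3
gamma: 0.05   mu: 1   lambda: 1   reg_mode: epsilon
outer sweeps: 27   converged: True
objective: 11.3533 -> 10.0585
active features (row norm > 0): 30
-----------------------------------------------------
rank  feature                   row l2 norm
   1  feature_0019                 0.368379
   2  feature_0011                 0.230462
   3  feature_0026                 0.225932
   4  feature_0006                 0.222229
   5  feature_0010                 0.000020
   6  feature_0004                 0.000008
```

The four planted markers (6, 11, 19, 26) head the ranking with weight-row
norms around 0.22–0.37, four orders of magnitude above everything else —
the transport regularizer has emptied the 26 inactive rows:

```python
print(support_recovery(res.rank_features(), inst.Z_true, k=4))   # 1.0
```

`res.predict(A_new)` returns scores on the original scale;
`res.plot_objective()` shows the descent trace. The same pipeline runs from
the shell:

```
wassreg simulate --m 30 --l 80 --n 3 --s 4 --seed 11 --out-dir sim
wassreg fit --features sim/A.csv --scores sim/Y.csv --method jwmr --lam 1 --out Z.csv
wassreg select --weights Z.csv --k 4 --out ranking.csv
wassreg evaluate --features sim/A.csv --scores sim/Y.csv --method ridge --k 4 --report report.csv
```

Every command writes a YAML sidecar (flags, seed, versions, objective
summary) so runs are reproducible bit for bit.

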
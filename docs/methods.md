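# Methods

## Problem and model

`wassreg` fits a multi-task linear model that predicts a matrix of cognitive
scores **Y** (l samples × n tasks) from a nonnegative imaging-feature matrix
**A** (m features × l samples) through a nonnegative weight matrix **Z**
(m × n), while selecting whole features. Instead of measuring the residual
and the weights with a matrix norm, both the empirical loss and the
row-sparsity regularizer are *entropy-smoothed, KL-relaxed optimal-transport
costs* over the n-dimensional score space:

    min_{Z >= 0}  Σ_{i=1..l} f_{(AᵀZ)^i, Y^i}(P^(i))  +  λ Σ_{j=1..m} f_{Z^j, t}(P̂^(j))

where, for source/target measures a, b and Gibbs kernel K = exp(−C/γ),

    f_{a,b}(P) = γ·KL(P | K) + μ·KL(P·1 | a) + μ·KL(Pᵀ·1 | b),

KL is the *generalized* (unnormalized) Kullback–Leibler divergence
KL(x, y) = ⟨x, log(x/y)⟩ + ⟨y − x, 1⟩, and C is a symmetric zero-diagonal
ground cost over score bins, rescaled to max entry 1. Each sample's predicted
score row is compared with its observed row as a discrete measure over the n
tasks, so the loss is sensitive to the geometry of score space (moving mass
to a nearby task is cheap, to a distant one expensive). Each feature's weight
row is transported toward a (near-)zero target measure t, so rows that the
loss does not need are emptied — transport-driven whole-feature selection.

The KL relaxation of the marginal constraints is essential twice over: raw
feature/score rows need not share total mass (so no histogram extraction is
needed — the histogram operator degenerates to a validated identity), and the
regularizer's zero-mass target would make hard marginal constraints
infeasible.

## Optimization

Block coordinate descent:

* **Plan block.** For fixed Z every plan is an independent unbalanced
  entropic transport problem, minimized *exactly* by the generalized Sinkhorn
  scaling u ← (a/(Kv))^ρ, v ← (b/(Kᵀu))^ρ with ρ = μ/(μ+γ). All l loss
  problems (and all m regularizer problems) share one kernel, so they are
  solved batched as n×B matrix recursions. For γ < 10⁻² the iteration runs in
  the log domain (log-sum-exp) to avoid kernel underflow; scaling vectors are
  floored at 10⁻³⁰⁰. Stopping: relative change of the scaling vectors below
  10⁻⁹ (balanced variant: sup-norm marginal violation below 10⁻⁹), cap 10⁴
  iterations, with a non-convergence flag rather than an exception.
* **Weight block.** For fixed plans the objective in Z reduces to
  g(Z) = μ Σ_i KL(c^(i) | (AᵀZ)^i) + λμ Σ_j KL(d^(j) | Z^j), with c, d the
  plans' row marginals — smooth and convex on Z ≥ ε_z. It is minimized by
  monotone accelerated projected gradient (FISTA with backtracking, momentum
  restart on any non-decreasing step), so the block value never increases.
  The entrywise gradient is
  μ Σ_i A_{ji}(1 − c^(i)_k/(AᵀZ)_{ik}) + λμ(1 − d^(j)_k/Z_{jk})
  (second term λμ in the analytic limit mode below); it is unit-tested
  against central finite differences.

Since the plan block is minimized globally and the weight block by descent,
the joint objective is non-increasing across sweeps; the fitted trace is
checked for this at 10⁻⁹ relative tolerance on every run of the test suite.

A separate *balanced* Sinkhorn (hard marginals, entropic value
⟨C,P⟩ − γe(P)) is kept as its own solver: it is the classical iteration for
the mass-balanced special case, and the relaxed solver provably approaches it
as μ → ∞ (verified numerically at μ = 10⁶ to 10⁻³ plan difference). The
exact LP oracle (`scipy.optimize.linprog`, HiGHS) anchors both.

## The zero-target regularizer

KL(·|0) is infinite for any nonzero mass, so the literal zero target is
handled two ways, selected by `reg_mode`:

* `"epsilon"` (default): target t = ε·1 with ε = 10⁻⁶. The printed algorithm
  stays runnable verbatim — regularizer plans are computed like loss plans.
* `"limit"`: the analytic ε → 0 limit. The plan collapses to 0 and the
  per-row penalty to γ·ΣK̂ + μ‖Z^j‖₁ — an entropic constant plus an l1 row
  penalty, with gradient λμ.

The two modes agree: at ε = 10⁻⁶ the epsilon-mode per-row penalty is within
1% of the closed form (measured ≈ 0.3%), and full fits in both modes reach
objectives within 1% of each other. The limit mode therefore serves as the
oracle for the default mode.

## Parameters

| name | meaning | default | rationale |
| --- | --- | --- | --- |
| γ (`gamma`) | entropic smoothing of every transport term | 0.05 | sharp plans without kernel underflow at cost scale 1 |
| μ (`mu`) | marginal-relaxation weight | 1.0 | balances transport fidelity against mass flexibility |
| λ (`lam`) | regularization weight (the tuned hyper-parameter) | 1.0 | swept over 10⁻⁴…10⁴ by the CV harness |
| ε (`eps_target`) | regularizer target level | 10⁻⁶ | close to the analytic limit, still well-conditioned |
| ε_z (`eps_z`) | weight positivity floor | 10⁻⁸ | the KL penalty's log needs Z > 0; entries ≤ 10ε_z report as 0 |
| `outer_tol`/`outer_max` | sweep stopping | 10⁻⁶ / 50 | objective changes plateau well before the cap on the sizes studied |
| `inner_tol`/`inner_max` | weight-block stopping | 10⁻⁸ / 500 | cheap at m×n weight sizes |
| `sink_tol`/`sink_max` | scaling-iteration stopping | 10⁻⁹ / 10⁴ | tight marginals at n ≤ a few dozen tasks |

One model-level inconsistency had to be resolved: the formulation places λ on
the regularizer in one statement and γ in another. Here λ is strictly the
regularization weight and γ strictly the entropic weight, which matches how a
single hyper-parameter is tuned on one grid in the evaluation protocol.
Similarly, the printed scaling iteration is the balanced one although the
model relaxes the marginals; both are implemented, the relaxed one (exponent
ρ) is what the model uses, and their μ → ∞ agreement is a test.

The ground metric over score space is not dictated by the model; two
constructions are provided: `"index"` (default), C_jk = (j−k)²/(n−1)² on the
task line — deterministic and data-independent — and `"data"`, squared
Euclidean distance between standardized score columns, normalized to max 1.

Initialization: Z⁰ is the ridge solution at λ_init = 1 clipped at ε_z (a
reproducible, data-driven warm start), plans from one exact plan update.
Scores are min-max scaled per column onto [0.01, 1] before fitting (KL needs
strict positivity; raw cognitive scales are arbitrary); the scaler is stored
and inverted for prediction. `scale_scores=False` opts out when the inputs
are already strictly positive measures.

## Feature selection and evaluation protocol

Features are ranked by descending l2 norm of their (floored) weight rows,
ties broken by original index. The evaluation harness reproduces the standard
comparison protocol: rank on training data, keep the top k, refit a ridge
predictor (with an unpenalized intercept, so score means are not shrunk away)
on the kept features, report per-task RMSE under nested five-fold
cross-validation. The inner five folds choose the selector's λ and the
predictor's ridge penalty from the nine-decade grid 10⁻⁴…10⁴ by mean inner
RMSE; test folds are never visible to any fitting or grid decision (enforced
structurally and by a mutation test). γ and μ stay fixed during tuning —
the protocol tunes a single hyper-parameter per method.

Baselines share the same data layout: closed-form ridge (normal equations,
Cholesky-verified nonsingularity) and l2,1-norm joint feature selection
solved by iteratively reweighted least squares with a 10⁻⁸ smoothing floor
on row norms (the smoothed objective is provably non-increasing; the solution
matches a derivative-free optimizer to 10⁻⁴ on small instances).

## Synthetic data: what it does and does not emulate

The generator mimics the *structure* of regional imaging-marker studies:
nonnegative features (|N(0,1)|, like gray-matter density or volumetric
values), a sparse nonnegative ground-truth weight matrix with exactly s
active unit-norm rows, scores AᵀZ* + N(0, σ²) clipped nonnegative and
min-max scaled per column to [0.01, 1]. Noise is applied before scaling, so
σ is interpreted on the pre-scaled score scale. The benchmark configuration
used throughout the tests is m=100 features, l=200 samples, n=5 tasks, s=10
active features, σ=0.05; smaller configurations (m=30, l=60, n=4) are used
where many repetitions are needed. It does **not** emulate inter-regional
covariance, longitudinal trajectories, diagnostic-group structure, or
feature-feature correlation of real imaging markers — so passing tests show
that the method recovers planted sparse structure under independent features
and moderate noise, not that it attains any particular accuracy on clinical
cohorts (which are access-restricted and not distributed with this package).

## Numerical choices and degenerate inputs

* 0·log 0 = 0 everywhere; KL returns +inf (not an exception) when the first
  argument has mass where the second has none.
* A measure of exactly zero mass in the relaxed solver returns the closed
  form P = 0, f = γΣK + μ(mass(a) + mass(b)).
* μ = 0 returns P = K, value 0 (only the entropic term remains).
* Constant score columns map to the mid-level 0.505 under scaling and invert
  back to the constant.
* Backtracking step underflow in the weight block returns the best iterate
  with a warning flag rather than failing the fit.

## Known limitations

* The objective is convex in each block but not jointly; the fit converges to
  a block-optimal point that depends on the (deterministic) initialization.
* Cost scale and γ interact: both provided ground costs are normalized to max
  entry 1 precisely so the γ default transfers across datasets; user-supplied
  unnormalized costs shift γ's meaning.
* The batched solver requires strictly positive marginals; the model
  guarantees this via the weight floor and score scaling, but it is not a
  general-purpose unbalanced OT routine (the single-problem solver is).
* Runtime grows linearly in l + m per sweep; the sizes studied (hundreds of
  features/samples, n ≤ a few dozen tasks) fit in seconds per fit, but n in
  the hundreds would call for a different plan representation.
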
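# Methods

## Problem and model

`rlcausal` estimates a directed acyclic graph (DAG) over d continuous
variables from an m × d observation table, then weights and prunes the
discovered edges.  The search treats graph construction as a one-shot
reinforcement-learning problem: a stochastic policy proposes adjacency
matrices, a scalar reward scores them, and policy-gradient updates
concentrate the proposal distribution on high-reward graphs.  Because
the maximum-reward graph ever sampled is retained, the procedure is a
guided stochastic search: the learned policy only has to make good
graphs likely, not certain.

### Likelihood and score

The BIC score needs a likelihood family; we use a Gaussian linear model
per node with its own residual variance — each node regressed on its
graph parents by ordinary least squares with an intercept.  The
node-local score is m·log(RSS/m) + k·log m with k = |parents| + 1
fitted mean parameters, which equals −2·(max log-likelihood) + k·log m
after dropping the constant m·(1 + log 2π) that is identical for every
graph and so cannot change any ranking.  The total score sums the
node-local terms (decomposability), and an in-memory cache keyed by
(node, parent set) makes repeated scoring cheap.  RSS is clamped below
at 1e-8·m so an exactly deterministic parent-child relation yields a
finite, strongly favourable score instead of −∞.

### Acyclicity

h(A) = trace(e^A) − d is computed with scipy's scaling-and-squaring
matrix exponential and compared to zero at tolerance 1e-8; a binary
adjacency matrix is acyclic iff h(A) = 0.  The independent check
`is_dag` uses Kahn-style elimination of in-degree-zero nodes; the test
suite verifies the equivalence exhaustively over all 3-node (64) and
4-node (4096) digraphs.

### Policy network

Each variable is represented by n_s observation rows (default 64)
drawn uniformly without replacement — the *same* rows for every
variable, so cross-variable dependence survives the subsampling — and
projected linearly to width d_model.  The encoder applies n_layers
blocks of multi-head self-attention and position-wise feedforward
sublayers, each wrapped as LayerNorm(x + Sublayer(x)).  No positional
encoding is added: variables are an unordered set and the encoder is
permutation-equivariant (tested numerically).  The decoder produces
one logit per ordered pair, uᵀ tanh(W₁ enc_i + W₂ enc_j); edges are
sampled independently Bernoulli(σ(logit)) with the diagonal forced to
zero.  Full-size defaults are 6 layers, d_model = 512, 8 heads,
d_ff = 4·d_model; all dimensions are configurable, and the bundled
benchmarks use a reduced network (2 layers, d_model = 16) that loses
nothing measurable at d ≤ 8.

The row subsample is drawn once per run by default.  Re-drawing it
every iteration (`resample_rows=True`) makes the policy input
non-stationary; a supervised probe (fitting a fixed target adjacency)
shows the network then cannot learn per-edge preferences within a few
thousand iterations, whereas with a fixed subsample it fits perfectly.
Since the subsample is seeded and of configurable size, fixing it
costs no generality.

### Reward scaling and penalties

Raw BIC values are dataset-scale (thousands of nats), which would force
per-dataset retuning of λ₁, λ₂.  With `score_normalization` (default
on), BIC is affinely mapped so the empty graph scores 0 and the
complete DAG in column order scores −1.  Both anchors are computed once
before training, so the reward is a *fixed* function of the graph for
the whole run — rewards from different iterations are comparable, the
best-so-far trace is a true running maximum, and the stored best record
satisfies reward = −(bic + λ₁·[not DAG] + λ₂·h) exactly on the
normalized scale.  (An online running min/max rescale was considered
and rejected: it makes rewards from different iterations incomparable.)
Defaults λ₁ = 1, λ₂ = 10 on this scale: any cyclic graph scores below
every DAG, and the smooth h-penalty gives the gradient a direction
toward acyclicity.

### Actor-critic updates

The critic mean-pools the d encoder vectors (permutation-invariant,
dimension-independent) and maps them through one tanh hidden layer to
a predicted reward; it is trained by mean-squared error against the
realized batch rewards with Adam, and its input is treated as constant
(no gradient flows from the critic loss into the policy).  The policy
ascends advantage-weighted log-probability, advantage = reward −
critic prediction, with the same Adam rule and learning rate (default
1e-3).  Two stabilizers are on by default:

* **advantage standardization** (`advantage_norm`): advantages are
  divided by their within-batch standard deviation.  Early batches are
  dominated by dense cyclic graphs whose h(A) penalties reach hundreds
  on the normalized scale; unscaled, those gradients slam every edge
  probability toward zero and exploration dies before any good graph
  is seen.
* **entropy bonus** (`entropy_weight`, default 0.2): the per-edge
  Bernoulli entropy is added to the objective (gradient contribution
  −p(1−p)·logit per logit), keeping edge probabilities away from
  saturation so the sampler keeps proposing local perturbations of the
  incumbent.  0.2 was chosen by a sweep over synthetic 5-node SEM
  instances; because the reward is normalized to unit scale, the value
  transfers across datasets.

Defaults: 32 graphs per iteration; 10⁴ iterations for full-size runs,
a few hundred to a few thousand for the bundled benchmarks.  All
randomness flows from a single integer seed; seeded runs are
bit-reproducible on the same platform.

### Exhaustive oracle

For d ≤ 5 an exact oracle enumerates every labeled DAG (25 / 543 /
29281 for d = 3/4/5, via chunked nilpotency filtering of all binary
digraphs) and returns the minimum-BIC record from a precomputed
node-local score table.  It is used only as an independent reference in
tests and the acceptance script, never inside the search.

## Edge strength

The spacing estimator Ŝ(X) = ψ(n) − ψ(1) + mean log adjacent spacing
is consistent for differential entropy and exactly affine-equivariant:
Ŝ(aX + b) = Ŝ(X) + log a for a > 0.  Everything is in natural log
(nats); the digamma correction is only consistent in that base.  The
IIE strength of an edge is the reciprocal absolute entropy gap of its
endpoints — computed on raw data it depends on measurement units,
computed after min–max normalization it is unit-free, which is why the
pipeline normalizes first (both variants are exposed).  Note the
statistic is symmetric: it weights an edge but cannot orient it.

Numerical choices: repeated sample values give zero spacings whose log
is undefined; the default `drop` policy removes them from the sum and
averages over the remaining count (an `epsilon` policy flooring
spacings at 1e-12 is provided for comparison — real survey columns
with many repeated codes make this choice material).  When two
variables' entropies coincide within 1e-12 the strength is capped at
1e12 and the edge kept, rather than erroring.  Pruning removes edges
with strength strictly below the threshold (default 0.5); a strength
exactly at the threshold survives.

## Normalization of the input table

Per-column min–max to [0, 1] is the default: the spacing estimator is
affine-equivariant, so a common bounded support makes entropies — and
hence strengths — comparable across variables of different physical
units.  z-scoring is available as an alternative.  Constant columns
are rejected by name (both rescalings and the entropy are undefined);
missing values and categorical codes are out of scope and must be
handled upstream.

## Synthetic benchmarks: what they show and what they don't

`rlcausal.synthetic` generates random DAGs (Bernoulli upper-triangular,
randomly permuted), linear Gaussian SEM data with edge weights of
magnitude Uniform[0.5, 2] and random sign (bounded away from zero so
structures are identifiable in practice), and unit-scale noise; the
empirical covariance is checked against the implied
(I−W)⁻ᵀ D (I−W)⁻¹.  Structural Hamming distance counts insertions,
deletions and reversals, a reversal costing 1.

These benchmarks exercise the full pipeline — search, scoring,
strength, pruning, I/O — under conditions where the ground truth is
known.  They do not emulate key features of real survey tables:
heavily tied/zero-coded columns (which stress the spacing-estimator
tie policy), non-Gaussian and nonlinear mechanisms (the BIC here is
linear-Gaussian), latent confounding, or selection effects.  A passing
benchmark therefore demonstrates correctness of the machinery and
recoverability under the stated model, not field validity on any
particular epidemiological dataset.  Note also that with unequal
residual variances a linear-Gaussian DAG is identifiable only up to
its Markov equivalence class: on some instances the *global* BIC
optimum differs from the generating graph by reversals, and no search,
however good, can do better than that optimum.

## Benchmark problem sizes

The bundled tests and the acceptance script use the reduced network on
m = 500 chain data (d = 3, 500 iterations × 32 graphs, three seeds,
compared against the exhaustive 25-DAG optimum at 0.1%) and m = 1000
random-SEM data (d = 5, 2000 iterations, pruned output compared to the
ground truth at SHD ≤ 2); entropy accuracy is measured at n = 5000
with 20 replicates.  These sizes give stable outcomes across seeds
while keeping a full run around a minute on one CPU.

## Known limitations

* Continuous data only; discrete or mixed tables need a different
  node-local score.
* The Bernoulli edge model samples edges independently given the
  encoder state; structured proposals (e.g. order-based) might explore
  large d more efficiently.
* λ annealing is not implemented (the penalty weights are fixed per
  run).
* Strength values depend on the tie policy and the normalization
  choice; published strengths computed with an unknown policy can
  differ systematically from ours even on identical data.
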
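# Methods

## Model and procedure

### Time-dependence test

A gene's expression series `x = (x_1, …, x_M)` at equally spaced time
points is modelled two ways:

- **AR(p)** (time-dependent): `x_m = β0 + β1 x_{m−p} + … + βp x_{m−1} + ε_m`,
  `ε_m ~ iid N(0, σ²)`, fitted by conditional least squares — the design
  matrix has rows `(1, x_r, …, x_{r+p−1})` for response `x_{p+r}` and the
  Gaussian MLE of `β` is the ordinary least-squares solution, with
  `σ̂² = ‖Y − Xβ̂‖²/(M−p)` (the MLE divisor, not the residual degrees of
  freedom).
- **Constant** (time-independent): `x_m = β0 + ε_m` over the same span
  `m = p+1…M`, so both models see the same `M − p` responses; `β̂0` is
  the span mean and `σ̂c²` the span variance with divisor `M − p`.

Because the constant model is nested in AR(p), the likelihood ratio
`Λ = (σ̂²/σ̂c²)^{(M−p)/2}` lies in `[0, 1]`, and

    F = (M − 2p − 1)/p · (σ̂c²/σ̂² − 1)

is referred to the `F(p, M − 2p − 1)` distribution. The order is unknown,
so all admissible orders are scanned (`p ≥ 1`, `p ≤ (M−1)/2` for a
full-rank design, `M − 2p − 1 ≥ 1` for a positive denominator degree of
freedom; at `M = 36` this is `p = 1…17`) and the gene is called
time-dependent when the **minimum** p-value across orders falls below `α`
(default 0.01). No multiple-testing correction is applied by default —
the decision rule is the literal minimum — but a Bonferroni option
(`bonferroni=True` / `--bonferroni`) divides `α` by the number of orders
actually tested.

**Span convention.** The constant model is fitted over `m = p+1…M`, not
`m = p…M`: the two models must share the response span for the nesting
(and hence `Λ ≤ 1`, `F ≥ 0`) to hold, and `M − p` observations are used
throughout.

**Calibration caveat.** The `F(p, M−2p−1)` reference is exact only for
fixed (error-independent) designs. In an autoregressive design the
regressors are lagged copies of the response, so the reference is
asymptotic: Monte-Carlo simulation (200,000 null replicates) puts the
true size of the nominal-0.05 test at ≈ 0.038 for `M = 20`, ≈ 0.043 at
`M = 36`, ≈ 0.049 at `M = 100`, converging to nominal as `M` grows. The
test is therefore slightly conservative on short series — it under-rejects,
never the reverse — which costs a little power but does not inflate the
set of "time-dependent" genes. The test suite pins both facts: the
finite-sample size at `M = 20` against the simulation value, and nominal
calibration plus p-value uniformity at `M = 200`.

### Degenerate series

- A rank-deficient design at order `p` (e.g. a constant series) skips
  that order; if every order is skipped the gene is called
  time-independent with p-value 1 — a flat series carries no time
  information.
- A series whose `p+1…M` span is constant but whose design is full rank
  scores `F = 0`, p-value 1 (both models fit exactly).
- `σ̂² = 0` with `σ̂c² > 0` (an exact AR fit) forces rejection: `F = +∞`,
  p-value 0. Numerically, a residual variance below `1e−12 · σ̂c²` is
  treated as exact, since least squares on an exactly-recursive series
  leaves only rounding noise.
- Profiles containing non-finite values are rejected with an error;
  the expression reader drops such rows with a logged warning before the
  test ever sees them (no imputation is attempted).

### Noise filter and activity thresholds

A gene is discarded as noise iff it is time-independent **and** its mean
expression is below a floor. "Very small mean" is not a universal
constant, so the floor defaults to the 20th percentile of the gene means
of the dataset at hand, overridable by an absolute value (`mean_floor`).
Both conditions are required: a dim but clearly periodic gene survives,
as does a bright flat one.

Each retained gene gets

    threshold = u + k·σ·(1 − F),   F = 1/(1 + σ²)

with `u`, `σ` the mean and **population** standard deviation (divisor
`M`) of its profile — `u` and `σ` are descriptive moments of a
fixed-length profile, not estimates of an infinite-population quantity —
and `k = 2.5` by default (allowed range `[0, 3]`). The damping `F`
interpolates between two regimes: for flat genes (`σ → 0`) the threshold
degenerates to the mean, and for volatile genes (`σ` large) it approaches
the classical `u + kσ` rule. Activity is **strict**: expression must
exceed the threshold, so ties — in particular every point of a constant
series — are inactive. Expression values are used as given; a
`log2(x+1)` preprocessing flag exists but is off by default.

### Active network

An edge of the static network is active at time `t` when both endpoints
are active at `t`. Proteins without an expression row are never active.
The per-time edge sets are retained and exportable (`u, v, t` triples),
but centralities are computed on their **union graph**: one score per
protein is needed to rank the proteome, which requires a single
aggregated graph. Per-time scoring remains available to users via the
per-time subgraphs. Self-interactions and duplicate edges are dropped at
load time; identifiers match case-sensitively unless uppercase
normalization is requested.

### Centralities

DC is the degree. BC sums `σ_st(v)/σ_st` over ordered distinct pairs
(each unordered pair counted twice — a constant factor, irrelevant to
ranks, fixed and documented). CC uses the component-local form
`(n_c − 1)/Σd` because active networks are frequently disconnected, and
isolated nodes score 0. SC is the diagonal of `exp(A)` computed by full
symmetric eigendecomposition — exact at these graph sizes, no series
truncation. LAC averages the degrees of a node's neighbors inside the
subgraph they induce. The edge clustering coefficient is
`ECC(u,v) = Z_{u,v}/min(d_u−1, d_v−1)` (triangles on the edge over the
maximum possible; a zero denominator — pendant edges — gives 0), and
NC(v) sums ECC over v's incident edges. Rankings are descending by score
with lexicographic tie-breaking, making every ranking deterministic.

### Evaluation

Top-k counts, cumulative jackknife curves (y = running count of true
essentials as the cutoff slides down the ranking) with trapezoidal AUC,
and overlap decompositions (S1, S2, shared S3) between two rankings.
The normalized AUC — raw AUC divided by that of the ideal
all-essentials-first ranking on the same node set — is an addition for
scale-free comparison; the raw AUC is reported alongside. Proteins absent
from a ranking (e.g. never-active proteins missing from the active
network) are appended after the ranked ones in lexicographic order, so
static-vs-active comparisons share a node universe; `ranked_only`
disables the padding. Essential lists are deduplicated and intersected
with the network's node set before scoring.

## Synthetic data: what it emulates and what it does not

`gen_ar_series` simulates the AR recursion with Gaussian innovations
(burn-in `10·p` steps from zero initial conditions, discarded, unless
explicit initial values are supplied); `gen_null_series` draws iid
normals. `gen_benchmark` builds a uniform random simple graph
(default 50 nodes, 120 edges), plants a module (default 10 genes) that is
strongly co-expressed in a short window (default 3 consecutive mid-series
time points out of 36), and labels essentials (default 15) by weighted
sampling without replacement — weight `enrichment` (default 3) inside the
module, 1 outside.

Module profiles sit at base level 5.0 with observation noise sd 0.05 and
a +10.0 boost inside the window: with these values the windowed points
exceed the gene's own threshold by a wide margin (threshold ≈ 11.9 vs
boosted level ≈ 15 at `k = 2.5`) and off-window points sit far below it,
so module genes are provably active exactly in the window. Background
genes are exactly constant at 0.01 by default — the time-independent,
very-small-mean noise genes the filter targets — and are provably never
active (a constant series never strictly exceeds its own mean). This
yields construction-guaranteed ground truth: the active union graph
equals the static subgraph induced on the module.

What the benchmark does **not** emulate: measurement-noise heteroscedasticity,
periodic (cell-cycle-like) expression shapes, partial expression
coverage, correlated essentiality and degree, or false-positive /
false-negative interactions. Passing tests therefore demonstrate the
correctness of the machinery and the directional behaviour of the method
under its own assumptions — not performance on real interactomes.

## Numerical and design choices

- AR fitting uses `numpy.linalg.lstsq`; rank is checked explicitly and
  rank-deficient orders are skipped per gene rather than failing the gene.
- Conditional least squares on AR(1) carries the classical `O(1/M)`
  downward bias (≈ `−(1+3β1)/M`), so parameter-recovery checks compare
  the mean estimate to the truth on the scale of the estimator's own
  sampling spread, not of the standard error of the mean.
- `F` is clamped at 0 against rounding (nesting guarantees `σ̂c² ≥ σ̂²`
  analytically); `Λ` is clamped into `[0, 1]`.
- Tie-breaking everywhere (rankings, padded tails) is lexicographic on
  the identifier string, making all outputs byte-reproducible; the
  pipeline writes a resolved-configuration JSON next to its outputs for
  provenance.
- The benchmark generator derives independent substreams (graph, module,
  expression, essentials) from one seed via `numpy.random.SeedSequence`,
  so outputs are bit-reproducible given the seed and any one component
  can change without perturbing the others.
- Problem sizes in the test and acceptance runs (10,000 null series for
  calibration, 200 × length-500 series for recovery, 500 replicates for
  power, 50-node benchmarks over 50 seeds) were chosen as the smallest
  sizes at which the binomial / sampling error bands are informative.

## Known limitations

- The minimum-p-value rule over ~17 orders inflates the per-gene
  time-dependence rate above `α` under the null (the orders are
  correlated but not identical tests); this is the documented decision
  rule, and the Bonferroni flag is the conservative alternative.
- The F-test size is below nominal for short series (see the calibration
  caveat); p-values at `M ≈ 20` should be read as slightly conservative.
- Aggregating the per-time active networks by union discards activity
  frequency: an edge active at one time point counts as much as one
  active at all of them.
- The percentile-based noise floor adapts to each dataset but is
  sensitive to heavy ties at the low end (with many identical dim genes
  the floor may equal their value and retain them; they remain inactive
  and thus harmless downstream).
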
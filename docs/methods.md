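# Methods

## Model

Family sizes evolve along a rooted species tree `T = (V, B)` as a
continuous-time Markov chain on counts `i ∈ {0, 1, 2, …}`: from state `i`
the chain gains a copy at rate `λ·i + κ` and loses one at rate `µ·i`, where
λ is the per-copy expansion (birth) rate, µ the per-copy loss (death) rate,
and κ a copy-number-independent gain (innovation) rate that lets families
arise from absence.  The family size at the root follows a Poisson
distribution with mean Φ.  Each branch `b` carries its own parameter set
`(t_b, λ_b, µ_b, κ_b)`; a family's profile is its vector of counts on the
leaf genomes.

Because a branch's kernel depends on its rates only through the products
`t·λ, t·µ, t·κ`, one branch parameter is redundant.  By default branch
durations are fixed (`t_b = 1`) and loss rates are free; the alternative
normalization (`µ_b = 1`, free durations) is available via
`normalization="unit_loss"`.

### Nested model classes

* **C** — one `(λ*, µ*, κ*)` for all branches and families, plus Φ
  (4 parameters).
* **L** — branch-specific rates (3|B| + 1 parameters).
* **FL** — every parameter is a product of a branch component and a family
  component; the family components of duration, expansion, loss and gain
  each follow a mean-1 gamma law discretized into `c` equal-probability
  categories represented by their conditional means (reported parameter
  count Σc + 3|B| + 1; 4c + 3|B| + 1 at uniform c).
* **FO** — family components over one constant branch component
  (Σc + 4 parameters).

The discretized family law is a finite equal-weight mixture: the family
likelihood averages the K = Πc_p component likelihoods over all category
combinations.  Family laws are constrained to mean 1 so that overall scale
is identified by the branch components and Φ; the free quantity per law is
the gamma shape.  The reported parameter count charges each category (the
conventional accounting for discretized-gamma models, and the one used for
the AIC/BIC tables); the internally optimized count (shapes instead of
categories) is exposed separately via `models.internal_parameter_count`.

### Likelihood

Profiles are assumed observable only when present in at least one leaf
genome, so by default each family likelihood is conditioned on non-absence
(divided by `1 − Pr[all leaves 0]`).  For mixture models the correction
conditions the mixture as a whole, since ascertainment acts on the observed
profile regardless of rate category.  The correction can be disabled
(`ascertainment=False`).

The likelihood is computed by the standard post-order (pruning) recursion
on a truncated count space `{0, …, M}`, with per-node rescaling of partial
likelihoods; log scale factors accumulate so small likelihoods never
underflow.  An impossible profile yields exactly −inf; the optimizer's
objective is penalized (never NaN) off the feasible manifold.

## Numerics

**Truncation.** The kernel on a branch is the matrix exponential of the
truncated generator (state M has no birth transition out), which is exactly
row-stochastic.  M is chosen per family as
`max(2 × largest leaf count, family total + 10)`, floored at 15; families
are grouped into M-buckets (24, 48, 96, 128, …) so that kernels are shared
within a bucket and only families that need a large state space pay for a
large kernel.  A tail audit checks the probability of reaching the boundary
from any observed start state; when it exceeds `tail_tolerance` (default
1e-8) the bound doubles, up to `max_bound`.  During optimization the
buckets are frozen (the final estimates are re-evaluated with the audited
bound); `max_bound` defaults to 128 at fit time because dense `expm` cost
grows roughly cubically (≈3 ms at M = 128, ≈175 ms at M = 384 on one core).
Datasets whose largest family exceeds the representable space raise an
explicit error telling the user to raise `max_bound`.

**Critical case λ = µ.** No closed-form kernels are used, so the critical
line needs no special casing: the matrix exponential of the truncated
generator is smooth in the rates, which matters because optimizers cross
λ ≈ µ routinely.

**Gamma discretization.** For shape α the mean-1 law Gamma(α, 1/α) is cut
at its c-quantiles; the category multiplier of slice `(a, b]` is
`c·[F_{α+1}(b) − F_{α+1}(a)]` with `F_{α+1}` the cdf of Gamma(α+1, 1/α),
which makes the multipliers average to exactly 1 (they are renormalized to
kill residual round-off).  As α → ∞ all multipliers approach 1; the spread
of four quartile means is ≈ 2.54/√α.

**Optimization.** Parameters are log-transformed (positivity by
construction) and maximized with L-BFGS-B (deterministic; numerical
gradients).  The outer stopping rule is the staged protocol's: iteration
ends when the gain in ln L between consecutive accepted iterates falls
below `tol_lnl = 0.01`; the iteration cap defaults to 10,000.  Box bounds:
rates in [1e-7, 50], Φ in [1e-8, 200] (bounded below because an all-absent
root degenerates the ascertainment correction), gamma shapes in
[1e-2, 1e6].  Branch kernels are cached by their effective
`(t, λ, µ, κ, M)`, so the coordinate perturbations of a numerical gradient
recompute only the kernels that changed.  Identical profiles are
deduplicated before pruning.  Per-family log-likelihoods are summed with
`fsum` over sorted values, making the dataset log-likelihood invariant to
profile order to the last bit.

**Staged estimation.** Models are fitted in order of increasing complexity
(default C → L → FL2 → FL3), each stage warm-started by embedding the
previous optimum: branch components carry over; family-law shapes absent in
the simpler model start at 1.0 by default.  A `degenerate_start` option
initializes new shapes at 1e4 instead (all multipliers ≈ 1), which places
the embedded point's likelihood within discretization round-off of the
simpler optimum — useful for verifying the nesting property
lnL(C) ≤ lnL(L) ≤ lnL(FL2) ≤ … (which then holds up to the 0.01 stopping
tolerance), but a poor starting point for actually estimating family
variation, because the likelihood surface is nearly flat in the shape at
the degenerate end.  Stage failures are recorded and do not abort the plan.

## Second pass: ancestral states and events

Given fitted parameters, an inside/outside pass yields for every family the
exact posterior of the count at each internal node (expected ancestral
family sizes are its means) and the joint posterior of (parent, child)
counts on every branch.  Events are **endpoint-defined** on that joint:
gain = Pr[0 → ≥1], loss = Pr[≥1 → 0], expansion = Pr[y > x ≥ 1],
contraction = Pr[x > y ≥ 1], remainder stasis — a 0→0 branch with an
intra-branch gain and loss counts no event, which keeps per-branch expected
event counts bounded by the number of families.  Under FL models,
per-combination posteriors are weighted by the posterior probability of the
combination given the profile (prior 1/K times component likelihood,
normalized).  Root content is summarized as the family-averaged posterior
fractions with 0, 1, and more than one (≥2) members.  Families whose
posterior fails numerically are excluded from aggregation and reported by
id, never dropped silently.

## Bootstrap

Estimator variance is assessed by the nonparametric bootstrap: each
replicate resamples the n families with replacement (replicate r seeds its
RNG with `base_seed + r`, so runs are reproducible and order-independent)
and reruns the full staged plan.  The across-replicate sample SD of each
estimator is reported as its bootstrap SE (both `sd` and `se` columns are
emitted; they coincide under this convention, which is stated explicitly
because "standard error" is sometimes divided by √R).  Replicates with any
estimator more than 9 sample SDs from the replicate mean are flagged;
flags are advisory and exclusion is an explicit option.  Note an algebraic
constraint: a single outlier's z-score is bounded by `(R−1)/√R`, so the
9-SD rule can only fire at all for R ≳ 83 — consistent with its use at
R = 100.

## Synthetic data

The forward simulator draws a Poisson(Φ) root count and evolves each branch
by exact jump-process (Gillespie) sampling of the birth-death-gain chain —
endpoint kernels are never used, so the simulator is an independent oracle
for the kernel code.  It records true states at every node, endpoint event
labels per branch (same definitions as the posterior pass), and the drawn
family multipliers.  Family multipliers can be drawn from continuous gamma
laws (model misspecification experiments) or from the discrete category law
(exact-model experiments).  With ascertainment on, all-zero families are
rejected and redrawn (the count is reported; > 99.9% rejection raises).
A hard cap of 10⁶ copies aborts runaway (sustained supercritical) settings
with an informative error.

### Study conditions emulated

The six-genome fixture uses the topology
`(((((Human,Mouse),Chick),DanRe),DroMe),CaeEl);` — fly sister to the
vertebrates, worm as outgroup — with unit branch times.  Default rates
emulate a metazoan domain-family regime: per-copy loss on average exceeding
birth, modest innovation, and (when heterogeneity is on) log-uniform
branch-to-branch variation of roughly an order of magnitude (λ ∈
[0.05, 0.6], µ ∈ [0.15, 1.5], κ ∈ [0.03, 0.5]); lineage rate variation at
that scale is what deep metazoan divergences exhibit and is required for a
lineage model to be detectably better than a constant one at the reduced
family counts used in testing.  Family heterogeneity for
model-comparison experiments uses skewed gamma laws on loss and gain
(shape ≈ 0.3–0.5); laws on duration or expansion are possible but can make
individual families supercritical for long stretches and are not used in
the default experiments.  Simulated mean family sizes land near the 3–9
range typical of real domain-family data.

**What the generator does not emulate:** annotation error (missed or
spurious domain hits), correlation between families, non-gamma family-rate
laws, rate change within a branch, and very large families (tens of
thousands of members) whose state spaces exceed the default fit-time
truncation cap.  Tests passing on this generator therefore validate the
estimation machinery under the model's own assumptions, not robustness to
real-data artifacts.

## Problem sizes

The test suite and the acceptance script run scaled-down versions of the
full protocol, as the package's own choice of test size: datasets of
50–2,000 families on the six-leaf topology, staged plans up to FL2/FL3,
bootstrap with 20–30 replicates (the protocol itself defaults to 100), and
10⁴ jump-process simulations per calibration grid point.  Constant-model
recovery uses n = 2,000 families; the qualitative C/L/FL comparison uses
n = 300 with both lineage and family heterogeneity.

## Known limitations

* Dense kernels make fitting cost grow steeply with the truncation bound;
  families of many hundreds of members need `max_bound` raised and
  correspondingly more time.
* Numerical gradients make high-category FL fits (K = Πc_p combinations)
  expensive; FL3 is practical at test scale, FL5 is slow.
* The reported bootstrap protocol refits the staged plan per replicate;
  with large plans this dominates runtime (replicates are embarrassingly
  parallel, but the implementation runs them serially for determinism).
* Branch lengths present in input Newick are deliberately ignored under the
  unit-time normalization; a warning is emitted.
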
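# Methods

This note documents the models, algorithms, numerical choices, and known
limitations behind `treesink`.

## The inference problem

A community is a binary vector over the tips of a rooted, time-calibrated
phylogeny, in an order that preserves clade monophyly.  We assume the
community assembled by a known process (filtering or limiting similarity)
acting on unobserved continuous traits, and we estimate the *effective
tree* of those traits: the branch-length transformation of the true tree
under which the traits would have evolved by plain Brownian motion (BM).
Estimates are conditional on the assumed assembly process and on the tree;
models trained on one topology do not transfer to another.  The approach
is also insensitive to the absolute evolutionary rate, because assembly
by *relative* distance to an optimum (select the k nearest) is invariant
to rescaling all trait distances; only the shape parameter is
identifiable, and a late-burst pattern cannot be distinguished from an
equivalent constrained (OU-like) pattern.

## Transformations

**Exponential rate-through-time (early/late burst).**  Rate at absolute
time *t* from the root is e^{a·t}; a branch spanning [t₁, t₂] gets length
(e^{a·t₂} − e^{a·t₁})/a, evaluated in the cancellation-free form
e^{a·t₁}·expm1(a·Δt)/a.  |a| < 1e−12 is treated as exactly 0 (the closed
form is 0/0) and returns a copy of the input tree.

**Delta.**  Node heights h (from the root) map to h^δ.  By default all
heights are then rescaled by a common factor so the maximum root-to-tip
depth is preserved (`preserve_depth=True`); the raw transform is available
behind the flag.  Depth preservation matches the common implementation
convention; nothing downstream depends on the choice because SES-MPD is
scale-free.

**Default gradient.**  81 values of a from −3 to 3: step 0.1 outside
[−1, 1] and 0.05 inside, where trees of ordinary depth are most
informative.  The delta gradient is the elementwise exponential of the
EB gradient (same stemmy-to-tippy sweep, δ > 0).

## Simulation stack

**Birth–death trees.**  Forward Gillespie simulation from a crown of two
lineages, per-lineage birth rate b and death rate d (defaults 0.8, 0.2);
the clock stops at the birth event that brings the extant count to the
target n; extinct lineages are pruned, unifurcations collapsed, and the
tree re-rooted at the most recent common ancestor of the survivors, so
results are exactly ultrametric.  Runs that go extinct first are retried
(up to 1000 attempts).  Tips are ordered by canonical ladderization —
children sorted by descendant count, ties by smallest tip label — so any
rotation of the same tree yields the same community-vector layout.

**Traits.**  BM tip values are root_state + P·ε, where P is the tip×edge
path-incidence matrix and ε are independent N(0, σ²·branch length) edge
deviates; σ² = 1 and root_state = 0 by default (the estimators are
invariant to both).  Each trait column draws from its own random stream
spawned from the seed, so adding traits never changes earlier columns.
Variants: perfectly covarying traits (one BM realization replicated
across columns) and block-structured traits evolved on several
differently-transformed effective trees.

**Assembly.**  Deterministic filtering presents the k species nearest a
trait optimum in Euclidean distance (ties to the earliest tip).  The
optimum is either the trait row of a uniformly drawn species — redrawn
per simulation — or the cross-species trait means.  Probabilistic
filtering samples k species without replacement with weight
e^{−λ·distance}, implemented as the exponential-race equivalence of
sequential weighted sampling evaluated in log space (keys log E_i +
λ·d_i), which is exact for any finite λ·d and cannot underflow; λ = 0 is
a uniform draw and λ → ∞ converges to the deterministic filter.  Limiting
similarity removes, one at a time, the species with the smallest summed
trait distance to all remaining species until k remain (the literal
"distance from all the others" criterion); a nearest-neighbour variant is
available behind a flag since either reading is defensible.

**Parameter draws.**  Per simulation a ~ N(0, sd), with sd = 5/tree-depth
by default: deeper trees reach the white-noise and stick-tree limits at
smaller |a|, and this rule keeps draws inside the informative range.
Experiments may truncate the draw; `truncation="reject"` resamples out-of-
bounds draws (an exact truncated normal), `"clip"` clamps them (used where
a clamped design is the stated protocol).  For probabilistic assembly the
draw must additionally be truncated above: at large positive a the trait
distances grow like e^{aT/2} and the selection weights e^{−λ·d} fall below
the smallest representable double and weighted sampling becomes
impossible, so probabilistic-assembly simulations in this family always
truncate the draw in practice.  The bound solves λ·scale(a) ≈ 600 with scale(a) = sqrt(2·n_traits·(e^{aT}−1)/a)
for the actual tree depth T, clamped to [1, 3]; negative draws only shrink
distances and are bounded at the gradient edge −3.

## SES-MPD and curves

MPD is the mean patristic distance over unordered present pairs.  SES-MPD
standardizes it against random same-size draws from the pool:
(obs − mean_null)/sd_null; negative values mean clustering.  Two null
modes:

* **permutation** — n_null Monte-Carlo draws (default 499); within a
  curve the same draws are reused at every grid point so curve shape
  reflects the transformation, not resampling noise;
* **analytic** — exact finite-population moments.  For a uniform k-subset
  the mean of MPD is the grand mean of pairwise distances, and the second
  moment splits over pairs-of-pairs sharing 2, 1, or 0 indices with
  inclusion probabilities k(k−1)/(n(n−1)), ·(k−2)/(n−2), ·(k−3)/(n−3).
  The unit tests verify these moments against exhaustive enumeration of
  all subsets.  Analytic mode makes 81-point curves for thousands of
  training communities affordable, because the moments depend only on
  (tree, grid, k) and are shared across communities.

A null sd below max(|mean|, 1)·1e−10 (star trees; community = whole pool,
where only float summation order varies) yields SES = 0 with a warning.

The curve-to-parameter model is OLS of a on the 81 curve values.  Adjacent
transforms are nearly collinear, so with fewer training curves than grid
points + 2 — or whenever the numerical rank is deficient — the fit falls
back to ridge (α = 0.01) with a warning.  Empirically the curve minimum
(the transformation of maximal clustering) is a monotone but upward-biased
readout of the generating a on 48–128-tip trees; the linear model absorbs
that offset, which is why it, and not the raw argmin, is the estimator.

## CKS estimator

Features: for each observation, gather all l−w+1 sliding windows of width
w, multiply by a frozen w×f standard-normal matrix, rectify, and average
across windows.  Binary presence/absence enters as 0/1 reals.  The
projection matrix is regenerated exactly from its seed, so models are
serializable without storing it, and each sweep cell derives its own
matrix deterministically from the base seed and cell index.

Readout: ridge regression with the intercept unpenalized (features
centered through the intercept).  The penalty is chosen by efficient
leave-one-out (generalized) cross-validation over a logarithmic grid
(1e−4…1e4, 17 points) unless a fixed penalty is supplied.  Centered-only
features are the default; standardization was evaluated and does not
change performance measurably on these inputs.

Hyperparameter sweep: windows by factors of 4 from 4 up to the data
length, feature counts up to 512, scored by the adjusted R² (p = 1) of
true-on-predicted on the validation split; cells wider than the data are
dropped.  Predictions are clamped to the training-target range.
Uncertainty: B bootstrap refits (default 100) on training rows resampled
with replacement, reusing the same projection matrix; the point estimate
is the mean of the B predictions and the interval their 2.5/97.5
percentiles.

## Validation experiments and problem sizes

`scripts/acceptance.py` and the heavier tests run the package's validation
designs at the following sizes, chosen so a full pass completes in a few
minutes on one CPU:

* trait covariance: 128-tip tree, 4000 simulations each for independent
  and perfectly covarying traits, a ~ N(0, 1) with the underflow
  truncation above, k = 64, λ = 0.5, 3000/1000 split;
* limiting similarity: 2000 simulations, a ~ N(0, 0.5), k = 32, 1350/650;
* probabilistic gradient: λ ∈ {0.05, 0.25, 0.5, 1.5, 5}, 1000 simulations
  per λ, k = 32;
* estimator comparisons: 2000 simulations (1200/800), k = 30, on 48- and
  128-tip trees; curve-structure check on a 64-tip tree with 200
  communities;
* pseudo-empirical workflow: a community generated at a = 0.05 on a
  64-tip tree, 800 training simulations, 100 bootstraps.

The multi-effective-tree scenarios (recovering the mean or maximum of 2
or 5 independent a values, λ = 3, k = 32) are implemented in
`run_sensitivity("multi_a_mean" / "multi_a_max")` with the same machinery.

## What the simulations do and do not show

The generator reproduces the study conditions the estimators are meant
for: one tree, one assembly process per dataset, equally sized
communities, traits that are exchangeable across simulations.  Passing
tests therefore demonstrate parameter recovery *under the assumed
generative model*.  They do not address mixed assembly processes,
abundance data, clade-heterogeneous rates, non-ultrametric or misestimated
trees, or communities whose size carries information — all outside the
model family.  On real data the estimate should be read comparatively
(early versus late burst) rather than as an absolute rate statement.

## Known limitations

* Estimator quality depends on the realized tree: R² at fixed design
  varies by several hundredths across birth–death realizations, and the
  N(0, 1) parameter range includes saturated (phylogenetically
  uninformative) tails on deep trees, which depresses validation R².
* The raw curve-minimum location is a noisy argmin on a 0.05/0.1 grid;
  its rank correlation with the generating parameter is ~0.65 at 200
  communities on a 64-tip tree even though its binned mean is cleanly
  monotone.  Use the linear curve model for point estimates.
* The birth–death simulator conditions on n by stopping at the nth birth
  (simple conditioning, not the generalized sampling approach); tree
  depths are correct to Monte-Carlo error against an independent
  event-queue implementation, but tail properties of the conditioned
  distribution are not guaranteed.
* `kitchen_sweep` shares nothing across cells, so sweeps are embarrassingly
  parallel in principle; the implementation is single-threaded.
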
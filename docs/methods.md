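# Methods

## Scope

`termevol` implements a comparative analysis of body-size evolution on
phylogenies that mix extant genus-level tips with extinct species-level
tips: Gaussian trait-model selection with genus-subsampling replication,
phylogenetic regression and variance statistics for social-complexity
traits, and stochastic character mapping of a binary caste trait. Analyses
run on the natural-log scale of head width (mm); root states are reported
both on the ln scale and back-transformed to mm.

## Trees and the phylogenetic covariance

A `Phylogeny` is an array-backed rooted tree with branch lengths in
arbitrary consistent time units. No ultrametricity is assumed: fossil tips
simply end early, and everything downstream (covariances, trend exposures,
transforms) is written for unequal tip depths. The phylogenetic covariance
`C` is assembled from a branch-tip incidence matrix, so the κ and δ
transforms reduce to reweighting branches. Pruning keeps the original root
even when it is left with a single child: the shared basal path length is
part of every pairwise covariance, and discarding it (re-rooting at the
MRCA of the retained tips) would silently change every model fit on a
pruned tree.

Zero-length branches are allowed (sampled-ancestor-like tips); if they make
`C` singular the Cholesky factorization fails with an explicit message
reporting the smallest eigenvalue and advising jitter, rather than
producing NaNs downstream.

## The candidate models and their likelihood

All seven models factor as `x ~ N(D·β, σ²·V₀(θ))`:

- **BM**: `D = 1`, `V₀ = C`; k = 2 parameters (σ², z₀).
- **trend**: `D = [1, T]` with `T` the tip depths. On an ultrametric tree
  `T` is constant, the design is rank deficient and the slope μ is
  confounded with z₀; the fit raises a `ConfoundedModelError` by default
  (the comparison pipeline drops the model and logs it) or, on request,
  reduces to the BM mean so the profiled maximum equals BM's.
- **trend+BM**: `D = [1, τ]` where the exposure `τ_i` sums the trend-regime
  branch lengths on tip i's root path. The designated clade's **crown**
  branches form the BM regime; its stem branch stays in the trend regime,
  because the directional size reduction is meant to run up to the origin
  of the clade (the opposite convention is one flag away,
  `paint_clade(..., include_stem=True)`). A single σ² is shared across
  regimes, so k = 3, consistent with treating the model as "trend plus BM
  with one extra parameter". On ultrametric trees the model stays
  identifiable (τ takes distinct values inside and outside the clade) and
  acts as a phylogenetically-weighted clade contrast.
- **OU**: single optimum with the root at the optimum (one mean parameter),
  `V₀_ij = (1/2α)·e^(−α·d_ij)·(1 − e^(−2α·C_ij))` with `d` the patristic
  distance — valid on non-ultrametric trees and equal to `C` in the α → 0
  limit. Exponential arguments are clamped at −745 so extreme α·T cannot
  overflow. The root-at-optimum convention mirrors the common
  single-optimum implementation in comparative-methods software and is the
  only OU variant offered.
- **λ / κ / δ**: Pagel transforms of `C`. λ scales off-diagonals
  (bounds [0, 1]); κ raises branch lengths to κ with 0^κ := 0
  (bounds [0, 1]; κ → 0 is speciational change); δ raises node ages from
  the root to δ (bounds (0, 3]) and then rescales the tree so the maximum
  tip depth is unchanged, keeping σ² comparable across δ. The bounds follow
  common defaults in the field and are configurable per fit.

The log-likelihood is the exact multivariate-normal density via a Cholesky
factorization (never an explicit inverse); the GLS mean parameters solve a
QR-factored whitened least-squares problem, and σ² profiles analytically as
RSS/n. Each fit is therefore a 1-D bounded optimization over the shape
parameter: a 9-point deterministic grid plus (by default) 5 seeded random
starts, followed by a global bounded scalar search and a local refinement
around the best start (`xatol` 1e-8); α is searched on the log scale with
bounds scaled by tree depth (default [1e-9, 50]/T). BM, trend and trend+BM
are closed form. Fits are deterministic for a fixed seed.

## Model comparison and replication

AICc = −2lnL + 2k + 2k(k+1)/(n−k−1); Akaike weights are computed within
each replicate and then averaged (not computed from mean AICc), so the
reported mean weight is the average relative support across sub-datasets.
Ties in best-model reporting break toward fewer parameters, then name.

The replication pipeline draws one species per modern genus uniformly at
random (fossil species always carried through), matches the sub-dataset to
the tree — modern tips at genus level via the genus token of the tip label,
fossil tips by full species name — prunes unmatched tips, fits the model
set, and summarizes each model's AICc, weight, root (mm) and shape
parameter as mean ± sd over replicates. With a single replicate the sd is
reported as 0. All per-replicate randomness derives from one seed via
`SeedSequence.spawn`, so summaries are bit-reproducible.

## PGLS and variance statistics

PGLS is GLS regression whose error covariance is `σ²·V₀` with `V₀` the BM
covariance or its λ/κ/δ transform; the transform parameter is profiled by
ML inside the regression (a 21-point grid plus bounded search), not
imported from the trait-model fits. Coefficient t statistics use the
unbiased residual variance on n−p degrees of freedom; the F statistic
compares the fitted design against the intercept-only model under the same
covariance, so t and F come from the same GLS projection. AIC counts the
coefficients, σ², and the transform parameter (omitted for BM);
`pgls_best` fits all four transforms and returns the minimum-AIC fit, ties
broken toward BM. A constant (or perfectly fitted) response degenerates t
and F; the fit warns and returns zeros rather than crashing.

Bartlett's homogeneity-of-variance test is delegated to
`scipy.stats.bartlett` behind a thin surface that adds the group-count
degrees of freedom and flags zero-variance groups (K infinite). Bartlett's
test ignores phylogenetic non-independence among species — there is no
standard phylogenetic equivalent — so every call emits a
`PhylogenyIgnoredWarning`. Variances are computed on the ln scale by
default with a raw-scale option, since either convention is defensible for
proportional data; `bartlett_by_group` reports the scale alongside the
statistic. Colony sizes are regressed on the log10 scale by the CLI (they
span orders of magnitude and are coarse estimates); the trait table keeps
the raw values.

Caste disparity is the proportional index `(a − b)/b`, positive exactly
when caste a is larger. Per-level intercept tests refit the best-transform
PGLS once per factor level with that level as the dummy-coding baseline, so
the intercept estimates the level mean; fitted values are invariant to the
baseline choice.

## Mk model and stochastic mapping

The binary social trait (true workers vs pseudergates) evolves under the
2-state equal-rates Mk process — for two states the equal-rates and
symmetric models coincide, and with the uniform root prior (the stationary
prior is identical here, both exposed) this is the simplest defensible
choice. The transition matrix has the analytic form
`P(t) = 1/2 ± 1/2·e^(−2qt)`; the likelihood is Felsenstein pruning, and the
ML rate is a 1-D bounded log-scale optimization (monomorphic data pin
q = 0 with a flag instead of an error).

Stochastic maps sample node states from their joint conditional
distribution (pruning pass, then root-to-tip sampling), and branch
histories conditional on endpoints by rejection sampling from the
unconditional process with a bounded retry budget (default 1e6), falling
back to exact uniformization: for the symmetric 2-state chain the
uniformized jump chain is the pure state swap, so the jump count only needs
the endpoint parity and jump times are uniform order statistics. Node-state
frequencies over maps estimate marginal ancestral-state probabilities; the
exact marginals (up-down pass) are also implemented and used to validate
convergence.

## Synthetic data: what it emulates, what it does not

The generator's defaults describe a termite-shaped study: a forward-time
birth–death tree (birth 1.0, death 0.5 per unit time) conditioned on 113
simultaneously extant lineages — the modern genus count — with each extinct
lineage retained as a fossil tip with probability 0.5, yielding roughly
140–190 total tips with a few dozen fossils; the stopping time is sampled
within the interval during which exactly the target number of lineages is
alive (stopping at the instant the target is reached would create two
zero-length sister tips). Traits are drawn exactly from the generating
model's multivariate normal via a Cholesky factor — one code path shared
with the likelihood constructions, no Euler stepping. Default generating
model: κ = 0.2 with z₀ = 0.84 ln mm (root ≈ 2.3 mm) and σ² = 0.05,
chosen so simulated ln head widths span roughly the variance observed in
real termite imago data (group variances of order 0.15–0.45). Each modern
genus tip expands into 1 + Poisson(2) species with ln-scale within-genus
sd 0.15 (congeners typically within ±20%); worker and soldier values
derive from the imago value through proportional-disparity offsets
(worker mean +0.25, soldier mean −0.10, sd 0.25), so configured disparities
are recovered by construction. Worker type (binary) and nesting type
(ternary) evolve by forward Mk simulation at rate 0.1; colony sizes are
lognormal.

Two deliberate simplifications matter for interpreting results on real
data. First, within-genus variation enters the subsampled datasets as an
**iid nugget** that none of the candidate models include; because the
simulated trees have short terminal branches, the λ model can absorb that
nugget and gains weight relative to the noiseless genus-level comparison,
and κ estimates bias low (sampling noise mimics speciational change). Real
genus-level trees have long terminal branches, which damps this effect but
does not remove it — a measurement-error variance term is the principled
fix and is explicitly out of scope. Second, the generator ties no trait
differences to the social annotations (worker type, nesting type evolve
independently of size), so social-statistics outputs on default synthetic
data are null calibrations, not effect reproductions.

## Problem sizes and determinism

The test suite and the acceptance script run entirely on synthetic data.
Replicated comparisons use 10–20 subsampling replicates and recovery
experiments 20–50 replicates on trees of ~150 tips — sizes chosen so a full
run completes in a few minutes on one CPU while leaving the Monte-Carlo
error of every reported rate well inside the margins being checked; the
originating study's 100-replicate design is the `n_rep` default and scales
linearly. Every random draw in the package flows through an explicit
`numpy` Generator or seed; identical seeds give bit-identical trees,
tables, fits and maps.

## Known limitations

- Single-optimum OU only; no multi-optimum or regime-dependent OU.
- One shared σ² in trend+BM; a two-rate variant would add a parameter the
  motivating single-"parameter" comparison does not support.
- No measurement-error / nugget variance term in the Gaussian models.
- Mk machinery is strictly 2-state; the generator's 3-state nesting trait
  is simulated forward but not fitted.
- Bartlett's test is phylogenetically naive by construction (flagged on
  every call).
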
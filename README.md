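# termevol

Phylogenetic comparative analysis of termite body size.

Termites (Blattodea: Isoptera) are eusocial cockroaches whose body size —
conventionally measured as head width in mm — has long been thought to have
undergone a unidirectional reduction as their societies grew more complex.
Testing that idea requires fitting competing models of continuous-trait
evolution on a phylogeny that includes **fossil tips** (extinct lineages
ending before the present make the tree non-ultrametric, which is what makes
a directional trend identifiable at all), handling species-level trait data
on a genus-level tree, and relating size to social-complexity traits.

`termevol` packages that workflow for comparative biologists:

- **Seven Gaussian trait-evolution models** on rooted, possibly
  non-ultrametric trees: Brownian motion (BM), BM with a directional trend,
  single-optimum Ornstein–Uhlenbeck (OU), Pagel's λ, κ and δ branch-length
  transforms, and a clade-mixed **trend+BM** model in which one designated
  clade (the higher termites, Termitidae, in the motivating analysis)
  evolves by plain BM while the rest of the tree carries a directional
  trend in the mean.
- **AICc model selection with Akaike weights**, replicated over
  one-species-per-genus subsamples to propagate within-genus variation.
- **PGLS** (phylogenetic generalized least squares) under ML-profiled
  branch-length transforms with AIC transform selection, **Bartlett
  variance tests**, proportional **caste-disparity** indices
  `(a − b)/b`, and pairwise caste correlations.
- **Mk-model ancestral states** for binary social traits (true workers vs
  pseudergates) with ML rate estimation and **stochastic character
  mapping**.
- A **synthetic-data generator** (birth–death trees with retained extinct
  tips, genus-structured species tables, exact multivariate-normal trait
  draws under every model) so the whole pipeline is testable end to end
  without any external data.

## The model family

Every candidate model defines a multivariate normal distribution of the tip
values x (ln head width):

    x ~ N(D·β, σ²·V₀(θ))

where `C` is the phylogenetic covariance matrix (`C_ij` = shared
root-path length of tips i and j, `C_ii = T_i` the tip depth) and

| model    | mean              | covariance V₀                    | extra parameter |
|----------|-------------------|----------------------------------|-----------------|
| BM       | z₀                | C                                | —               |
| trend    | z₀ + μ·T_i        | C                                | μ               |
| trend+BM | z₀ + μ·τ_i        | C                                | μ               |
| OU       | z₀ (at optimum)   | (1/2α)e^(−α d_ij)(1 − e^(−2αC_ij)) | α             |
| λ        | z₀                | off-diagonals of C scaled by λ   | λ ∈ [0,1]       |
| κ        | z₀                | C with branch lengths b → b^κ    | κ ∈ [0,1]       |
| δ        | z₀                | C with node ages t → t^δ (rescaled) | δ ∈ (0,3]    |

`τ_i` is the trend *exposure*: the summed length of the branches on tip i's
root path painted with the trend regime. Because σ² and the mean parameters
profile analytically out of the Gaussian likelihood, each fit reduces to a
one-dimensional bounded optimization over the shape parameter; BM and the
trend models are closed form. AICc uses k = 2 for BM and k = 3 for the
others, and Akaike weights are `exp(−Δᵢ/2)` normalized over the model set.

## Worked example

Simulate a study-shaped dataset — 113 modern genus tips plus retained
fossil tips evolving under the speciational κ model (κ = 0.2, root
exp(0.84) ≈ 2.3 mm) — then run the replicated genus-subsampling comparison:

```python
import numpy as np
from termevol import SimConfig, simulate_dataset, replicate_fit
from termevol.simulate import default_clade_painting

cfg = SimConfig(seed=42)
tree, table, _ = simulate_dataset(cfg)          # <Phylogeny: 180 tips, non-ultrametric>
painting = default_clade_painting(tree)
clade = sorted(np.asarray(tree.tip_labels)[
    painting.trend_exposure() < tree.tip_depths() - 1e-9])
summary = replicate_fit(table, tree, n_rep=10, seed=0, clade_tips=clade)
print(summary.summary()[["weight_mean", "weight_sd",
                         "root_mm_mean", "parameter_mean"]].round(4))
```

```
          weight_mean  weight_sd  root_mm_mean  parameter_mean
model
kappa          0.9978     0.0016        2.3294          0.1200
lambda         0.0022     0.0016        2.4054          0.9482
OU             0.0000     0.0000        2.2725          3.0702
delta          0.0000     0.0000        2.5726          2.9516
BM             0.0000     0.0000        2.4165             NaN
trend          0.0000     0.0000        2.3257          0.0226
trend_BM       0.0000     0.0000        2.3582          0.0145
```

The generating κ model takes essentially all the Akaike weight
(mean ± sd over the 10 subsampling replicates), the back-transformed root
estimate (2.33 mm) recovers the generating root, and the directional trend
models collapse — the behaviour expected when fossil tips are present and
size divergence tracks speciation events rather than time.

The same steps are available from the shell:

```bash
termevol simulate --seed 42 --out run/
termevol fit-models --tree run/tree.nwk --traits run/traits.tsv \
    --n-rep 10 --seed 0 --out run/fits/
termevol social-stats --tree run/tree.nwk --traits run/traits.tsv --out run/social/
termevol simmap --tree run/tree.nwk --traits run/traits.tsv --out run/asr/
```

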
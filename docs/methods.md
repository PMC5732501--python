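# Methods

## Model

The package fits the BYM Poisson log-linear model for areal counts:
`y_i ~ Po(E_i e^{η_i})` with `η_i = α + β x_i + γ_i + ε_i`. The structured
effect γ has the intrinsic CAR prior with conditional mean equal to the
weighted average of the other areas' effects and conditional variance
`σ_γ² / Σ_j w_ij`, identified by the constraint `Σ γ_i = 0`. The weights
matrix W is the *unstandardised* symmetric matrix produced by the weights
module; the division by row sums inside the conditional plays the role of
row standardisation. ε is iid Gaussian.

Priors (all configurable in `BYMConfig`, notation is (mean, variance)):
`α, β ~ N(0, 100)` — weakly informative on the log-risk scale;
`σ_ε ~ N(0, 10)` truncated to (0, ∞) — a half-normal with scale √10, generous
for log-scale noise; `σ_γ² ~ Gamma(3, 1)` (shape/rate), putting most mass on
variances of order 1–5, consistent with the expectation that well-chosen
neighbours have similar effects. The benchmark model B is the same model with
γ removed (`include_structured=False`); it shares every code path.

### Identifiability rebalancing

γ and ε are confounded in the likelihood (only their sum enters η). After
sampling, the package computes the excess-variation share
`ψ = S(γ) / (S(γ) + S(ε))`, where S(·) is the standard deviation across areas
of the per-area posterior medians (chains pooled by default; a per-chain
variant is available), and transforms every stored draw:
`γ ← γ − ψ·ε`, `ε ← ε + ψ·ε`. The update is applied exactly in this printed
form. Note that the second assignment *inflates* ε rather than transferring
the removed variation to it; the transformation nevertheless conserves γ+ε
per draw and area (to one floating-point rounding), so η, relative risks and
DIC3 are invariant to it. It is a relabelling of the two random-effect
surfaces, not a change of the fitted risk.

## Sampler

A Metropolis-within-Gibbs scheme compiled with numba:

- γ: single-site random-walk Metropolis against the exact ICAR full
  conditional times the site's Poisson likelihood, swept in index order.
  After each sweep γ is recentred to sum to zero over non-island areas and
  the removed mean is added to α (standard ICAR practice; η is unchanged).
- ε: single-site random-walk Metropolis against `N(0, σ_ε²)` times the
  likelihood.
- α, β: random-walk Metropolis with the full likelihood.
- σ_γ², σ_ε: random-walk Metropolis on the log scale. With a Gamma prior on
  the *variance*, the σ_γ² full conditional is generalized inverse Gaussian,
  not Gamma, so no Gibbs step is used. The ICAR pseudo-likelihood uses rank
  N−1 (connected non-island subgraph assumed; islands are excluded and their
  γ pinned to 0 with a warning).

All six proposal scales adapt every 50 iterations during burn-in only
(multiplicative steps targeting 44% acceptance); after burn-in the scales are
frozen, so the stored chain is a valid time-homogeneous Markov chain. Chains
are initialised from scaled-down overdispersed prior draws
(α, β ~ N(0,1); γ, ε ~ N(0, 0.25²); σ's from their priors) with chain-indexed
sub-seeds — a literal draw from the N(0,100) priors can overflow the first
likelihood evaluation. Defaults mirror the reference analysis: 2 chains,
25,000 post-burn-in iterations thinned by 5 after a 10,000-iteration burn-in.

Correctness checks: with the likelihood term disabled the sampler reproduces
its priors (the acceptance suite verifies the Gamma(3,1) moments of σ_γ² at
50,000 draws within batch-means Monte-Carlo error), and on data simulated
from the model itself (exact ICAR draws via the spectral decomposition in
`sample_icar`) the 95% credible interval for β achieves nominal coverage.

Known limitation: when γ explains almost all structure, σ_ε concentrates near
zero and its log-scale walk mixes slowly; R-hat on σ_ε is the usual flag (the
pipeline marks fits with max R-hat above 1.1). This is the familiar BYM
weak-identifiability pathology, and it barely affects DIC3, β, or the risk
surface.

## Weights matrices

All 17 specifications return symmetric, nonnegative, zero-diagonal,
*unstandardised* matrices; `row_standardise` is a separate step used for
Moran's I and neighbour profiles, mirroring software that standardises
automatically. Decay parameters are data-driven: `λ = 10 / mean(d_ij)` over
ordered pairs i≠j and `b = 1/λ`, recomputed from covariate distances for the
C family and from hybrid distances for the H family — this makes D4/D5
invariant to the distance unit (asserted to 1e-12 in tests). Inverse-power
kernels hit non-finite values at zero distances (coincident centroids, tied
covariates); per row these are replaced by the row's maximum finite value,
then the lower triangle is overwritten by the transpose of the upper triangle
to restore symmetry. A row with no finite off-diagonal entry is an error
rather than silently patched. The A2 order weights are the decreasing vector
(e⁰, e^−0.5, e^−1) on shortest-path orders 1–3 of the queen contiguity graph;
ω is exposed as a parameter. Islands survive construction with zero rows and
a warning; the model pins their γ to 0.

## Synthetic data generator

The generator emulates three risk-surface regimes on a 12×12 lattice by
additive log-scale components: `log μ = log E + β_gen·x̃ + usrf + noise`,
`y ~ Po(μ)` (optionally rounded instead). The underlying spatial random
field (USRF) is:

- **noise** — iid `N(0, 0.7²)`;
- **smooth** — a proper-CAR draw (precision `D − 0.99·A`, queen adjacency)
  passed through 4 neighbourhood-averaging convolution passes and rescaled to
  sd 0.7. The convolution is essential: a raw first-order CAR draw on a
  12×12 grid has Moran's I ≈ 0.4 and does not look like a smooth surface;
  after convolution I ≈ 0.9;
- **clusters** — a convolution of two fields: a large-scale CAR draw
  (ρ = 0.9, 3 convolution passes) thresholded at its 75th percentile into a
  high region, multiplied by a correlated positive field
  `exp(GMRF(sd 0.2))` at height 1.1, plus background noise (sd 0.08). With
  the defaults the high region forms ≈4 contiguous patches (93% of seeds fall
  in 2–6 patches).

The covariate is `x = 0.5·usrf + N(0, 0.3²)`, giving a moderate correlation
(≈0.5–0.8 across seeds and regimes) with the field — strong enough to make
covariate-space smoothing meaningful, weak enough that the structured effect
still has work to do. Log-expected counts come from the mixture
`0.9·N(2, 0.15²) + 0.1·(2 + Gamma(2, 4))`: most E near e² ≈ 7.4 with a few
modestly larger values. Observation noise sd is 0.1. Counts are Poisson
rather than rounded because the fitted likelihood is Poisson.

Every component is a pure function of (config, seed); sub-seeds are derived
deterministically per component, and the study pipeline derives per-(dataset,
spec) seeds by hashing, so adding a model never perturbs the others.

What the generator does *not* emulate: irregular area geometries and sizes,
externally standardised expected counts, covariates with their own spatial
structure independent of the field, and overdispersion beyond the log-normal
noise component. A green regime-contract test therefore establishes that the
methods behave correctly on lattice worlds of this kind, not that any real
map will show the same orderings.

Measured regime contracts (100 seeds, 19,999 permutations, A1 weights, counts
scale): noise — p > 0.05 in ~96% of seeds; smooth — p < 1e-4 in 100%;
clusters — p < 1e-4 in ~91%.

## Evaluation

- **DIC3** = `−4·Ê[log f(y|θ)] + 2·Σ_i log (1/M)Σ_m f(y_i|θ^m)`, chains
  pooled; per-area density averages are computed with log-sum-exp so large
  counts cannot underflow. At M = 1 it collapses to −2 log f.
- **Moran's I** on row-standardised weights by default (raw optional), with
  a two-sided permutation p-value around the null expectation −1/(N−1),
  add-one rule, default 9,999 permutations (exact tests at small N; a
  fixed-seed permutation stream makes it reproducible). Residual adequacy is
  Moran's I on the posterior-mean ε after rebalancing, always with A1
  weights regardless of the fitted specification.
- **Gelman–Rubin** R̂ in the classic between/within form (no rank
  normalisation, no splitting); cross-checked against arviz's "identity"
  method in the test suite.
- Model comparison tables sort by DIC3 and flag models within 2 units of the
  best as "similar fit".

## Numerical choices and edge cases

- Contiguity uses exact index arithmetic on lattices and shapely predicates
  on polygons, with a snap tolerance (default 1e-9) for floating-point
  boundary matching; rook contiguity requires a shared boundary of positive
  length, queen accepts point contact.
- Unreachable pairs in the adjacency-order matrix carry the sentinel −1.
- Coincident centroids yield zero distances by design (nested areas); the
  sanitisation rule above absorbs the resulting infinities.
- Permutation tests and all random draws take explicit integer seeds below
  2³¹; identical inputs give bit-identical outputs.
- The Moran's I comparison `≥ threshold` in the neighbour profile counts a
  neighbour whose weight equals the threshold, matching "excluding areas
  with weights less than the threshold".

## Known limitations

- Proposal adaptation is global per parameter block, not per site; extremely
  heterogeneous row sums could mix unevenly (not observed on the study
  worlds).
- The ICAR rank correction assumes one connected non-island component;
  heavily fragmented maps get a warning and a slightly diffuse σ_γ².
- ESRI shapefile input is not supported (no reader in the dependency set);
  GeoJSON and GAL cover the same use cases.
- Dense-kernel specifications (D1, D2, A2 on large neighbourhoods) smooth
  towards near-global means; on fields like the study's smooth regime they
  buy little over the benchmark, and the DIC3 gap between them and the local
  specifications (A1, D3, D5) is correspondingly large.
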
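# bymweights

Bayesian disease mapping with configurable spatial weights matrices.

Small-area counts of disease incidence or mortality are noisy: rare events and
small populations make raw rates unstable, and nearby areas tend to be alike.
The standard remedy is the Besag–York–Mollié (BYM) model, which smooths
area-level relative risks towards their neighbours through an intrinsic
conditional autoregressive (ICAR) prior. At the heart of that prior sits a
spatial weights matrix **W** — and the choice of **W** can change the analysis
dramatically. This package exists to study exactly that: it builds 17
different weights specifications, fits the BYM model under each of them by
MCMC, generates synthetic areal data with known spatial structure, and
compares the resulting fits.

It is aimed at spatial epidemiologists and biostatisticians who want to probe
the sensitivity of disease-mapping conclusions to the weights specification,
on their own data or on simulated risk surfaces.

## The model

Counts follow a Poisson likelihood with a log-linear relative risk:

```
y_i ~ Poisson(E_i · exp(η_i)),        η_i = α + β x_i + γ_i + ε_i
```

where `E_i` are expected counts (supplied, or computed from populations by
internal standardisation `E_i = (Σy/ΣP)·P_i`), `x_i` is an areal covariate,
`ε_i ~ N(0, σ_ε²)` is unstructured noise, and the structured effect γ carries
the ICAR prior

```
γ_i | γ_{−i} ~ N( Σ_j w_ij γ_j / Σ_j w_ij ,  σ_γ² / Σ_j w_ij ),    Σ_i γ_i = 0.
```

Priors: `α, β ~ N(0, 100)`; `σ_ε` half-normal with scale² = 10;
`σ_γ² ~ Gamma(3, 1)`. A benchmark model ("B") drops γ entirely. Because γ and
ε are only weakly identified, stored draws are rebalanced: with
`ψ = S(γ)/(S(γ)+S(ε))` (S = sd across areas of the per-area posterior
medians), each draw is transformed `γ ← γ − ψ·ε`, `ε ← ε + ψ·ε`, which leaves
γ+ε and all risk summaries unchanged.

The 17 weights specifications: binary first-order adjacency (A1), third-order
adjacency with decaying order weights (A2), inverse distance to the powers
1, 2, 5 (D1–D3), exponential decay `exp(−λd)` (D4) and Gaussian decay
`exp(−d²/2b²)` (D5) with `λ = 10/mean(d)`, `b = 1/λ`, plus the same five
kernels on covariate distances `δ_ij = |x_i − x_j|` (C1–C5) and on hybrid
distances `d_ij·δ_ij` (H1–H5). Models are compared by DIC3 (the Celeux et al.
variant of the deviance information criterion) and by Moran's I permutation
tests on posterior-mean residuals.

## Worked example

```sh
python examples/fit_bym.py
```

fits A1 and the benchmark B to a smooth-field synthetic data set and prints:

```
model A1: DIC3 = 711.4, residual Moran p = 0.9626, max R-hat = 1.728
  rank correlation of posterior-mean structured effect with the true field: 0.92
  posterior mean beta = 1.79
model B: DIC3 = 730.4, residual Moran p = 0.0001, max R-hat = 1.003

model dataset       dic3  mean_deviance  morans_I  morans_p  delta_dic  similar_fit
   A1  smooth 711.434892     681.354076 -0.004987    0.9626    0.00000         True
    B  smooth 730.373753     693.753218  0.189844    0.0001   18.93886        False
```

Read: spatial smoothing with first-order adjacency weights improves DIC3 by
about 19 units over no smoothing, its residuals pass the spatial-independence
check (Moran p = 0.96 — no leftover autocorrelation), and the posterior-mean
structured effect tracks the latent field that generated the data (rank
correlation 0.92). The benchmark's residuals are still strongly
autocorrelated (p = 0.0001). The other examples build weights matrices and
neighbour profiles (`weights_matrices.py`), generate the three synthetic
regimes (`synthetic_data.py`), and run a miniature multi-model study with all
artefacts written to disk (`full_study.py`).

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the synthetic data sets from scratch and recomputes the headline
quantities: the observed-count Moran's I permutation p-values for the
smooth-field and clustered regimes under binary first-order weights, and the
minimum DIC3 improvement over the no-smoothing benchmark across the adjacency
and geographic-distance models on the smooth-field data set. Results are
written as JSON keyed by quantity.
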
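# s3reg — spatially smooth sparse regression for spatial omics

`s3reg` estimates **location-specific regression coefficient fields** linking a
spatial response feature (for example a target gene's expression across a
tissue section) to a high-dimensional set of spatial predictors (transcription
factors, other genes, deconvolved cell-type proportions, neighbourhood or
niche context).  It is aimed at spatial transcriptomics analysts who want to
know not merely *where* a feature is high, but *how relationships between
features change across the tissue* — which regulators matter in which layer,
which cell type carries a gene's expression at which location, and which
cell-type pairs deploy gene programs in a spatially coordinated way.

## Model

At locations $s_1,\dots,s_n \in \mathbb{R}^2$ the response follows a varying-
coefficient model

$$y(s_i) = \sum_{k=1}^{p} x_k(s_i)\,\beta_k(s_i) + \epsilon(s_i),$$

which is hopelessly under-determined (one observation per location) without
structure.  The stacked field $\beta \in \mathbb{R}^{pn}$ is estimated by
minimising

$$\frac1n \sum_{i=1}^n\Big(y(s_i)-\sum_k x_k(s_i)\beta_k(s_i)\Big)^2
\;+\;\lambda_1 \sum_{k=1}^p \lVert H\beta_k\rVert_1
\;+\;\lambda_2 \sum_{k=1}^p \lVert \beta_k\rVert_1
\;+\;\lambda_3 \sum_{k=1}^p \sqrt{n}\,\lVert \beta_k\rVert_2 ,$$

where $H$ is the $m\times n$ edge–node incidence operator of a spatial graph
— a k-nearest-neighbour graph for small sections or a Euclidean minimum
spanning tree (only $n-1$ edges, full connectivity) for large ones.  The
fused term makes each coefficient surface piecewise-constant with sharp
boundaries where the data demand them; the $\ell_1$ term gives
location-level sparsity (a predictor may be active only in some regions);
the group-$\ell_2$ term removes globally irrelevant predictors.  The convex
objective is minimised by an adaptive-moment (Adam) first-order method with
cosine learning-rate annealing, gradient clipping and early stopping.

Around the core fit the package provides:

- **penalty selection** by spatially blocked cross-validation with
  log-uniform (optionally adaptive) search over $(\lambda_1,\lambda_2,\lambda_3)$;
- **post-hoc selection**: cluster-wise OLS refits with BH-adjusted t-tests
  that zero coefficients not significantly different from zero;
- **cell-type attribution**: regressing a gene on deconvolved cell-type
  proportions, with non-negativity and presence constraints, to obtain
  per-cell-type expression surfaces;
- **SVG detection**: Moran's I with permutation significance on attributed
  surfaces, BH-corrected over (gene, cell type) pairs;
- **cross-cell-type covariation**: Spearman correlation between attributed
  gene surfaces of two cell types, permutation-tested, FDR- and effect-size-
  filtered, aggregated across sections into a (gene, gene, cell type,
  cell type) tensor whose per-pair mean count of significant gene pairs acts
  as an interaction strength;
- **context features**: 30-nearest-neighbour cell-type composition vectors
  and k-means niches for microenvironment-aware predictor matrices;
- a **simulator** of piecewise-constant coefficient fields with known
  clusters and active sets, plus recovery scoring (ARI, precision/recall,
  RMSE).

## Worked example

`examples/01_simulate_and_fit.py` simulates a 300-spot section with 20
predictors (3 truly active, coefficients constant within each cell of a
2-cell Voronoi partition), tunes the penalties by spatially blocked CV, fits
and screens the field:

```text
simulated 300 spots x 20 predictors; active predictors: ['g0003', 'g0004', 'g0017']
tuned penalties: lambda1=3.66e-03, lambda2=1.69e-06, lambda3=1.37e-03
final objective: 3.2568 after 3000 iterations
selected predictors after post-hoc tests: ['g0003', 'g0004', 'g0017']
cluster recovery ARI = 0.883  (1 = perfect recovery of the true spatial partition)
selection precision = 1.00, recall = 1.00; RMSE on truly-active coefficients = 0.587
```

The pipeline recovers exactly the three active predictors, and k-means on
the fitted coefficient surfaces reproduces the true spatial partition almost
perfectly (ARI 0.88).  The other scripts in `examples/` demonstrate penalty
tuning, cell-type attribution, SVG detection, the covariation tensor and
context features, each printing the quantities it computes.

A thin CLI mirrors the library (`s3reg simulate|fit|tune|posthoc|attribute|svg|covary`);
every run writes a YAML manifest with its configuration, seed and input
checksums.

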
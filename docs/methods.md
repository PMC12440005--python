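# Methods

## Model and estimation

`s3reg` fits the spatially varying-coefficient model
`y(s_i) = Σ_k x_k(s_i) β_k(s_i) + ε(s_i)` over `n` planar locations by
minimising a composite convex objective: a mean-squared data term plus three
penalties — a graph-fused `ℓ1` term `λ1 Σ_k ‖Hβ_k‖₁` on edgewise coefficient
differences, an element-wise `ℓ1` term `λ2 Σ_k ‖β_k‖₁`, and a group-`ℓ2`
term `λ3 Σ_k w ‖β_k‖₂` with group weight `w = √n` by default (the standard
group-lasso group-size weight; each group is one predictor's length-`n`
coefficient vector, and `w` is exposed as `PenaltyConfig.group_weight` for
users who prefer a different convention).  With one observation per location
the unpenalised problem is under-determined; the fused term shares strength
between neighbouring locations while allowing sharp boundaries, the `ℓ1`
term lets the active predictor set change across space, and the group term
removes predictors wholesale.

**Spatial graph.**  The fused penalty runs over the edges of either a
symmetrized k-nearest-neighbour graph (default `k = 7`) or a Euclidean
minimum spanning tree.  The `auto` policy uses KNN for sections of at most
1000 locations and the MST above that, since the MST carries the penalty
with only `n − 1` terms.  Both constructions break distance ties toward the
lexicographically smaller node pair, so gridded coordinates give a unique,
reproducible edge set.  The MST is built by Kruskal's algorithm over
candidate edges sorted by `(weight, i, j)`; for large inputs candidates are
restricted to the Delaunay triangulation (which contains the Euclidean MST),
with an all-pairs fallback for degenerate layouts such as collinear points.
A disconnected KNN graph is allowed — the penalty then smooths within
components — and `SpatialGraph.n_components()` lets callers check.

**Optimiser.**  The objective is minimised with an Adam-style
adaptive-moment method: subgradients for the `ℓ1` and fused terms (the
subgradient at 0 is taken as 0) and an ε-smoothed surrogate
`√(‖β_k‖² + ε)`, ε = 1e−8, for the group norm to avoid instability near
zero.  Defaults: zero initialisation (the objective is convex, so the
optimum does not depend on the start), learning rate 0.01 with cosine
annealing, global-norm gradient clipping at 5.0, `max_iter = 5000`.  The
monitored objective (trace, incumbent tracking, early stopping) is the
*exact* non-smoothed objective, so the final recorded value equals an
independent re-evaluation of the returned field to machine precision.
Early-stopping checks run every 25 iterations with patience 50 checks and
tolerance 1e−6; periodic (rather than per-iteration) checks matter because
the first adaptive-moment steps transiently inflate the fused term before
the objective drops below its zero-field value.  Because subgradient
methods leave tiny nonzeros, fields are hard-thresholded at
`1e−6 × max|β̂|` before any downstream step.  Fits are bit-reproducible
given a seed and configuration.

**Standardization.**  Penalties are scale-sensitive, so the pipeline
z-scores predictors and mean-centres the response before fitting and maps
coefficients back to the raw predictor scale (`β_k = β'_k / sd(x_k)`).
`fit_s3r` itself operates on the data exactly as given — this keeps the
invariant that the recorded objective equals the objective of the returned
field, which could not hold if the fit silently transformed its inputs.  No
intercept is included; response centring plays that role.  Missing values
are refused rather than imputed, and the optional `log_normalize` flag
(default off) applies `log1p` at load time.

## Penalty selection

`(λ1, λ2, λ3)` are chosen by spatially blocked cross-validation: k-means on
the coordinates forms 10 spatially coherent blocks dealt round-robin into 5
folds, so validation sets are spatially contiguous regions and spatial
autocorrelation cannot leak fitted structure into the score.  Because the
coefficient field is undefined at held-out locations, a validation spot is
predicted with the coefficients of its nearest training spot — consistent
with the smoothness assumption, and documented as a choice.  The CV loss is
validation MSE, matching the data term.  Trials sample the triple
log-uniformly on `[1e−6, 1e2]`; the reference backend is plain random
search (`n_trials = 50` by default), and an `adaptive` backend with the same
contract (every trial recorded; best = minimum mean validation MSE, exact
ties to the more regularised triple) spends the first third of its budget
exploring log-uniformly and the rest in a shrinking log-normal
neighbourhood of the incumbent.  On a range spanning eight decades per
dimension the adaptive sampler reaches good triples with a third of the
trials random search needs, which is why the pipeline uses it by default.

## Post-hoc selection

Penalised estimates carry shrinkage bias and no standard errors.  Retained
coefficients are therefore screened by unpenalised refits: the section is
split into spatial clusters (k-means on coordinates, default
`max(10, n/50)` clusters, assuming nearby locations share coefficient
scales), and within each cluster the response is regressed (OLS, intercept
included) on the predictors whose fitted column is nonzero anywhere in the
cluster.  Two-sided t-test p-values are shared by all spots of a cluster
and BH-adjusted jointly across every (cluster, predictor) test — the
stricter scope, controlling the FDR of the full selection rather than per
cluster.  Entries with adjusted p ≥ α (default 0.05) are zeroed.  Clusters
with more candidates than spots are rank deficient; their tests are skipped
with a warning and remain unselected.  Testing predictors active anywhere
in the cluster (rather than only at a given spot) is deliberate: selection
is cluster-granular by construction.

## Cell-type attribution and downstream read-outs

**Attribution.**  Regressing one gene's spot-level expression on deconvolved
cell-type proportions yields per-spot, per-cell-type coefficients read as
the cell type's contribution to that gene at that location.  After fitting
(on the standardized scale; raw-scale coefficients reported) and post-hoc
selection, two biological constraints are enforced: negative coefficients
are shrunk to zero (a cell type cannot remove expression) and positive
coefficients are zeroed wherever the cell type's proportion is zero (an
absent cell type contributes nothing).  Default penalties are deliberately
light (λ1 = 1e−3, λ2 = λ3 = 1e−4 on the standardized scale, chosen so that a
known generative level is recovered with under 10 % shrinkage bias); real
analyses should tune by blocked CV.

**SVG detection.**  Moran's I,
`I = (n/S0) Σ_ij w_ij z_i z_j / Σ_i z_i²` with row-standardized binary
adjacency of the fitting graph, is computed per attributed (gene, cell type)
surface; significance is a one-sided permutation test
(`p = (1 + #{I_perm ≥ I_obs})/(B + 1)`, default `B = 999`) because only
positive autocorrelation indicates spatial structure, with BH correction
over all tested pairs.  Columns with fewer than two distinct values are
skipped.

**Covariation.**  For cell types C1, C2 and genes G1, G2 the statistic is
the Spearman correlation across spots between the two attributed surfaces.
Genes with fewer than 3 nonzero spots in a cell type are skipped.  The null
is a two-sided spot-permutation test (default 999 permutations) of one
field, BH-corrected within the cell-type pair; a pair is significant iff
FDR < 0.05 *and* `|ρ| ≥ 0.3` (effect-size floor; smoothed surfaces produce
many tiny but "significant" correlations).  Since the surfaces are
spatially smoothed, rank correlation is used as a pragmatic stand-in for
spatially aware association measures; spatially structured nulls are out of
scope and a known limitation.  Per-section significant pairs are binarized
into a (gene, gene, cell type, cell type) tensor with canonical ordering —
(G1, G2, C1, C2) and (G2, G1, C2, C1) are the same association and stored
once.  A pair *replicates* when significant in ≥ 2 sections (configurable),
and the interaction strength of a cell-type pair is the arithmetic mean
over sections of its count of significant gene pairs.

**Context features.**  Per cell, the relative cell-type frequencies among
its 30 nearest neighbours (self excluded) form a local composition vector;
k-means with K = 5 over these vectors defines mesoscale niches, returned as
one-hot indicators for use alongside gene-level predictors.

## Simulator

The generator emulates the structure the model is built for: coordinates
uniform on the unit square; a spatial partition (Voronoi cells of random
centres by default, horizontal bands or a checkerboard as alternatives);
for each of `n_active` active predictors a coefficient drawn per cluster
from the nonzero integer grid `{−c, …, c} \ {0}` (default `c = 2`), redrawn
until no two clusters share a coefficient vector so the partition is
identifiable; predictors i.i.d. standard normal; Gaussian noise (default
sd 0.5, against per-predictor signal of magnitude 1–2).  Everything is a
pure function of the seed.  What it does **not** emulate: count noise and
mean–variance coupling of sequencing data, spatially correlated predictors,
collinearity between cell-type proportions, gradual (non-piecewise)
coefficient gradients, and irregular spot lattices.  Passing recovery tests
therefore demonstrates correctness of the estimation machinery under the
model's own assumptions, not robustness to all real-data pathologies.

Recovery is scored by (i) ARI between the true partition and k-means (true
number of clusters, benchmark convention) on the fitted field restricted to
truly active columns, (ii) precision/recall of the post-hoc-selected
predictor set against the true active set, and (iii) RMSE over truly-active
entries.  Under the default conditions (300 spots, 20 predictors, 3 active,
2 Voronoi clusters, noise sd 0.5) the tuned pipeline reaches median ARI
≈ 0.85–0.91 with precision and recall at or near 1 across replicate seeds,
as recomputed by `scripts/acceptance.py` and the acceptance test suite.

## Numerical and design notes

- **Prevalence filter**: predictors nonzero in *fewer than* 10 % of spots
  are removed; exactly 10 % is retained (strict-less removal).  The filter
  is idempotent.
- **Expression orientation** is explicit (`spots_by_genes` /
  `genes_by_spots`); there is no autodetection, because silent transposition
  is a classic failure mode.
- **Row alignment** is always by spot identifier with a sorted-id order
  imposed, so input row permutations cannot change results; mismatched id
  sets are an error naming the offenders.
- **Ties**: KNN neighbour ties break toward the smaller node index; MST
  weight ties toward the lexicographically smaller pair; CV-score ties
  toward the more regularised triple.
- **Degenerate inputs**: constant vectors are rejected by Moran's I;
  duplicate coordinates are allowed in graphs (zero-weight edges); an
  all-zero attribution column simply yields no tests.
- **Problem sizes** in the test and acceptance runs (300-spot sections,
  8–10 replicate seeds, 199–999 permutations, 500 null replicates) were
  chosen as the smallest sizes at which the benchmarked properties are
  stable; all are plain parameters and scale up directly.
- **Known limitations**: single-response fitting (multi-response is a loop);
  no selective-inference correction after selection (the post-hoc refit is a
  pragmatic screen, not a debiased estimator); permutation nulls ignore
  spatial autocorrelation of the surfaces being tested; attribution quality
  is bounded by the quality of the supplied deconvolution proportions.
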
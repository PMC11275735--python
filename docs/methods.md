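# Methods

This note documents the models and procedures implemented in
`spatialclocks`, the choices made where the design was genuinely open, and
what the synthetic-data validation does and does not demonstrate.

## Data model

A dataset is an `AnnData`: raw transcript counts in `X` (cells × genes),
derived matrices in `layers` (`volnorm`, `lognorm`, `scaled`, `smoothed`),
and per-cell metadata in `obs` (centroid `x`/`y` in µm, segmentation
`volume` in µm³, `cell_type`, `animal_id`, `sample_id` = one tissue
section, `age_months`, optional `region`/`subregion`/`condition`/
`doublet_score`). Coordinates live in a per-section frame; no distance is
ever computed across sections.

## Preprocessing

QC rules are applied in a fixed order: doublet score ≥ 0.18 (when scores
are provided; doublet scoring itself is out of scope and hooked in as a
column), volume ≤ 100 µm³ or ≥ 3× the median, total counts ≤ 20, detected
genes ≤ 5, and finally — after pooling all sections — the top and bottom
2% of total expression. The trim bounds are quantiles of the data being
filtered; because re-quantiling a filtered dataset would trim again, the
bounds actually used are recorded in the returned ledger and can be passed
back explicitly, which makes re-application a no-op. Whether totals are
volume-normalized before trimming is configurable (`trim_on_volnorm`,
default off: raw totals).

Log-normalization scales each cell to a total of 250 and applies
ln(1 + v); the pseudocount is 1 and the log is natural, the convention of
the standard single-cell toolchain. Z-scaling uses the population
(ddof = 0) standard deviation and truncates values at +10 after scaling;
zero-variance genes map to 0.

## SpatialSmooth

For one cell type and section, each cell is connected to its
min(k, n−1) nearest same-type neighbours (Euclidean, k = 20 by default;
k = 5 for subregion-restricted clocks). The adjacency is directed — no
symmetrization — and L1 row-normalized into the propagation matrix S.
Expression is smoothed by iterating

    X_{t+1} = (1 − α) X + α S X_t ,  α = 0.8,

from X₀ = X until the sup-norm change is below 0.01 or 30 iterations have
elapsed. For α < 1 the map is a contraction; its fixed point
X\* = (1 − α)(I − α S)⁻¹ X is implemented as a dense-solve oracle used in
tests. A section with a single cell of a type gets a unit self-loop so S
stays row-stochastic and the fixed point returns the cell's own value
(a zero row would instead shrink it by 1 − α). Every smoothed value is a
convex combination of input values within its connected component, which
the test suite asserts on random graphs.

## Aging clocks

A clock for one cell type is per-gene standardization followed by lasso
regression of chronological age (months) on smoothed log-normalized
expression. The penalty is selected by internal 5-fold cross-validation
over a 20-value log-spaced path with a data-driven maximum (the smallest
penalty that zeroes all coefficients, the standard behaviour of the
toolchain's `LassoCV`), `max_iter` 10000, and the final model is refit on
all training cells. Internal CV folds are plain k-fold on cells by
default, with an animal-grouped option (`group_folds_by_animal`).

Evaluation is leave-one-animal-out: the held-out animal's cells are
predicted by a clock trained on the remaining animals. Because smoothing
graphs never span sections and partitions are whole animals, smoothing
each partition separately is identical to smoothing each section once;
standardization and the lasso are refit per fold, so no information leaks
from test to train (asserted by mutating held-out cells and checking
train-side invariance). Metrics: cell-level Pearson R and MAE, and the
animal-level Pearson r of median predicted age versus age.

Age acceleration is the cell's predicted age minus the mean predicted age
of its (sample, cell type) group, hence exactly mean-zero per group.
Predicted ages are not clipped.

For external datasets the panel is intersected with the clock's genes,
log-normalization repeated with the same scheme, smoothing applied per
type (for non-spatial data, each cell is replaced by the mean of 20
randomly drawn same-type, same-animal cells — the pseudocell fallback),
and missing clock genes are filled by a pluggable imputer; the default is
per-gene training-mean fill, which contributes exactly zero after
standardization (reference-based imputation such as SpaGE is out of scope
but fits the interface). Negative imputed values are clipped to zero. A
coverage report (< 20% observed clock genes warns, or errors in strict
mode) accompanies predictions.

Two non-spatial variants are provided: a pseudobulk clock trained on 1000
bootstrap means of 30 cells per animal ("SingleCell (PB)"), and
prediction without the smoothing step ("SingleCell (SS)" — a spatially
trained clock applied to unsmoothed profiles).

Intervention effects are differences in median predicted age
(intervention minus control), with an optional intercept added to the
intervention predictions to correct a mean-age mismatch between arms,
plus two-sided Mann-Whitney tests at the cell level and on per-animal
medians. Regional comparisons with fewer than 50 cells in either arm are
flagged insufficient.

## Regions and distance cutoffs

Subregions are annotated by clustering each cell's neighbourhood
composition: counts of every cell type within 100 µm (same section), PCA
(components covering 95% variance by default; a fixed count is also
accepted — the source procedure does not state one), then k-means with
k = 25 and a fixed seed. Merging the clusters into named subregions is an
explicit user mapping, mirroring a manual step.

The proximity cutoff for a subregion is the mean, across samples, of the
per-sample median Delaunay edge length within that subregion. Edges whose
endpoints lie in different subregions count for both (a drop option
exists); edges are not length-pruned for cutoff estimation, since the
median is robust to rare long hull edges.

## Proximity effects

For an (effector, target) pair: each cell's nearest-effector distance is
computed per section, with self-exclusion when effector = target.
Within each (sample, subregion) stratum, target cells strictly below the
subregion cutoff are "Near" and are matched 1:1 (the natural reading of
"matched"; the ratio is not stated in the source) to "Far" targets
strictly beyond the cutoff — by default the farthest ones, alternatively
a seeded uniform draw or a greedy match on total raw counts (cells whose
totals are closest to the Near mean). The area-restricted variant labels
Near inside the open annulus (outer − 15 µm, outer). The effect is
Cohen's d of age acceleration, Near minus Far, in the two-sample
pooled-sd form (per-group ddof = 1), with a Student's t-test (Welch
optional) and a Brown–Forsythe Levene diagnostic (`center="median"`,
`proportiontocut=0.05`) available for the equal-variance assumption.
Pairs with fewer than 50 Near or 50 Far cells are filtered out. The
average proximity effect (APE) of an effector is the mean d over its
surviving targets; target impact is the mean |d| per target.

The spatial permutation null permutes coordinates within each sample
(equivalent to shuffling type labels) and recomputes the screen; 20
permutations with per-permutation seeds drawn uniformly from [0, 50000]
under master seed 444, summarized by median and 2.5–97.5% interval.
Gradation profiles rescale all cutoffs by unit distances u (area-
restricted: outer = u·cutoff, inner = outer − 15 µm). Glial
activation/inflammation subtypes are defined by summing log-normalized
expression over signature genes and labelling the top fraction (0.2% by
default, ties broken by cell index) as subtype-positive; the refined
labels can be used as effector/target categories.

### Why months-recovery uses the non-smoothed variant

Graph smoothing averages each Near cell with its ~20 nearest same-type
neighbours, most of which lie outside a ~30 µm effect radius, so smoothed
predictions dilute a planted local age shift several-fold by design (the
screen still detects and ranks it). The quantitative check that a planted
+3-month shift is recovered in months therefore uses the package's
non-smoothed prediction variant ("SingleCell (SS)"), which is exactly the
tool the framework provides for removing that dilution; the ranking,
sign, and significance checks use the standard smoothed predictions.

## GIN perturbation model

Per section, a Delaunay graph is built and edges above 200 µm pruned.
Local graphs are induced 2-hop subgraphs around up to 100 sampled centers
per cell type per section, optionally augmented by re-centering on every
node of the first round (deduplicated on center). Node features are
one-hot cell types over the fixed 18-type vocabulary; the label is the
mean age acceleration over the subgraph's cells (cells of types without a
clock carry no acceleration and are excluded from the mean).

The regressor is a three-layer graph isomorphism network: per layer,
aggregation h ← h + Σ_neighbours h, then linear → 16, batch
normalization, ReLU, linear 16 → 16; ReLU after the first two layers; sum
pooling; final linear to a scalar. Training uses a balanced MSE — labels
binned into 10 equal-width bins, samples weighted by inverse bin
frequency normalized to mean 1 — with Adam at lr 1e-4, batch size 64, 50
epochs, and a seeded 90/10 validation split. The network is implemented
directly in numpy (forward, manual backpropagation, Adam, batch-norm
running statistics); gradients are verified against numerical
differentiation in the test suite.

Numerical choices: the readout weights start at zero so initial
predictions sit at the origin of the label scale rather than amplifying
random pooled sums; normalized balance weights are clipped at 10× the
mean, because a near-empty bin otherwise hands a single graph a weight
orders of magnitude above the rest and stalls training; mini-batches are
materialized once from a seeded shuffle and only their visiting order is
reshuffled per epoch, so the sparse block structures can be cached.
Inference runs in eval mode (running batch-norm statistics) and uses
canonically ordered (per-column sorted) summation for aggregation and
pooling, making model output *exactly* invariant to node relabelling —
not merely up to floating-point noise.

Perturbations mutate only the center's one-hot: loss-of-function draws a
uniformly random other type, gain-of-function sets a specified type
(graphs already centered on that type are excluded); the effect is
perturbed minus unperturbed predicted neighbourhood aging. Geometry is
never modified, and eval-mode batch-norm makes effects deterministic.

## Trajectories and aging genes

A trajectory is the mean expression of one (gene, cell type, subregion)
at each profiled age, on volume-normalized counts scaled to the median
per-cell total (this analysis' own normalization, distinct from the
lognorm-to-250 used by the clocks). Combinations present in fewer than
70% of ages are dropped; gaps are filled last-value-carried-forward, with
leading gaps back-filled from the first observed age (pure LOCF is
undefined there). Rows are standardized and clustered with k-means
(k = 9, seed 444); archetype naming is left to the user. Display
smoothing uses a cubic smoothing spline (s = 20 by default; s = 0
interpolates).

The aging-gene screen correlates per-sample pseudobulk (mean lognorm per
cell type) with age by Spearman's ρ; the 95% CI uses the Fisher
z-transform with SE 1/√(n−3) (a bootstrap CI is available behind a flag).
"Increasing" requires ρ > 0.3 with CI lower bound > 0, mirrored for
"Decreasing". The regional-change statistic takes the 5 youngest and 5
oldest animals, downsamples each cell type to the minimum count over
mouse × region (types under 20 cells excluded; low-count regions such as
the ventricles can be excluded explicitly), forms mouse × region profiles
(mean volnorm → renormalize to 250 → log1p), and reports the mean over
genes of |old − young| in natural-log units (divide by ln 2 for a log2
axis), averaged over 20 downsampling repeats with a 95% interval.

## The synthetic generator

The generator emulates the documented statistical structure of a
brain-wide spatial aging study: 20 ages tiling 3.4–34.2 months (one
animal per age by default, one section per animal), ~2000–2500 cells per
1.5 mm² section (giving Delaunay neighbour distances of ~30 µm, the
scale of the real cutoffs), 18 cell types with aging proportion trends
(microglia, oligodendrocytes, T cells up; OPCs, NSCs, neuroblasts down),
four subregion rectangles with distinct type mixtures (white-matter-like,
cortex-like, striatum-like, ventricle-like), and a 300-gene panel of
which 50 genes per cell type carry age programs with slopes ±0.04 per
month on the log NB mean (dispersion θ = 20; lognormal volumes, median
500 µm³). Counts are negative-binomial with mean
volume × baseline × exp(slope × (effective age − mean age)), so a linear
model on log-normalized data is well specified and clock-recovery tests
are sharp rather than model-misspecification tests.

Planted proximity effects shift the *effective transcriptomic age* of
target cells within a radius of an effector cell — through the same
expression programs as aging, which is precisely the construct the clocks
claim to detect. Condition pairs shift effective age per cell type in one
arm. The generator does not simulate optical crowding, segmentation
error, transcript spillover, batch effects, or cell-type
misclassification; passing the recovery tests therefore demonstrates the
statistical machinery is correct and unbiased under a well-specified
model, not that real-data effect sizes will be as large or as clean.

## Problem sizes used in validation

The test suite and acceptance script size their simulations to the
package's own validation needs: clock recovery on 20 ages × 1200
cells/section; planted proximity recovery on 20 ages × 2500 cells/section
(≈50k cells, ≥5000 target cells per screened pair); gradation decay on
ten replicate 6-age datasets; the GIN on 20000 counting-rule graphs —
chosen to emulate the augmented local-graph corpus scale of a real
section dataset, since at the fixed optimizer settings (lr 1e-4, 50
epochs, batch 64) the training-step budget scales with corpus size; and
the full-pipeline determinism check on a 50k-cell dataset.

## Known limitations

* Cluster→subregion merging and archetype naming are manual steps by
  design; the package ships mechanisms, not labels.
* The balanced-MSE reference implementation is not public; inverse-bin
  weighting with clipping is our reading of it.
* The pseudocell fallback draws random same-type cells rather than
  expression-space neighbours; with only 300 panel genes the difference
  is minor, but it is a simplification.
* Mediation analyses, reference-based imputation, GO enrichment, doublet
  scoring, and transcript-spillover estimation are intentionally out of
  scope; hooks exist where they would plug in.
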
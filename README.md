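# spatialclocks

Spatial single-cell transcriptomic aging clocks for MERFISH-like data:
graph-smoothed per-cell-type age prediction, cell-proximity effects on
aging with matched controls and spatial permutation nulls, in-silico
cell-type perturbation with a graph neural network, and spatiotemporal
expression trajectory analysis. A first-class synthetic-data module
generates datasets with planted ground truth (age programs, proportion
trends, proximity effects of known magnitude in months) so the entire
pipeline is testable end-to-end without any downloads.

The package is aimed at computational biologists analysing imaging-based
spatial transcriptomics of aging tissue — a cell × gene count matrix with
per-cell centroids, segmentation volumes, cell types, animal IDs and ages
— and at methodologists who want a tested reference implementation of the
spatial aging clock framework.

## The model

**SpatialSmooth.** For each cell type, cells are linked to their k = 20
nearest same-type neighbours within a tissue section, giving an
L1-row-normalized adjacency S. Log-normalized expression X is smoothed by
iterating

```
X_{t+1} = (1 − α) X + α S X_t ,   α = 0.8
```

to convergence (sup-norm tolerance 0.01, at most 30 iterations). For
α < 1 this is a contraction with fixed point (1 − α)(I − α S)⁻¹X.

**Clocks.** A cell-type-specific clock is per-gene standardization
followed by lasso regression of chronological age on smoothed expression,
with the penalty chosen by 5-fold CV over a 20-value path. The *age
acceleration* of cell *i* in the set Q of cells sharing its sample and
cell type is

```
AgeAccel_i = PredictedAge_i − E[ PredictedAge_j | j ∈ Q ]
```

**Proximity effects.** For an effector → target pair, target cells nearer
to an effector than the subregion-specific cutoff (mean across samples of
median Delaunay neighbour distance) are "Near" and matched 1:1 per
(sample, subregion) stratum to "Far" targets beyond the cutoff. The
effect is Cohen's d of age acceleration (Near − Far, pooled sd), filtered
at ≥50 cells per group; an effector's average proximity effect (APE) is
its mean d over surviving targets. Controls: spatial permutation nulls
(20 permutations, seeds drawn from [0, 50000] under master seed 444),
area-restricted annuli (inner radius = outer − 15 µm), random and
count-matched Far definitions, and distance-gradation profiles.

**In-silico perturbation.** A three-layer graph isomorphism network
(hidden width 16, sum pooling, balanced MSE, Adam lr 1e-4, batch 64, 50
epochs) predicts neighbourhood aging — mean age acceleration of a local
2-hop cell graph — from one-hot cell types; mutating the center cell's
type simulates loss- or gain-of-function of a cell type.

See `docs/methods.md` for assumptions, parameter defaults and numerical
choices.

## Worked example

```python
import spatialclocks as spc

# a synthetic 10-age study with a planted pro-aging T cell effect:
# targets within 30 um of a T cell age +3 months transcriptomically
truth = spc.default_truth(
    seed=1, n_ages=10, cells_per_section=1000,
    effector_rules=[spc.EffectorRule("T cell", None, 30.0, +3.0)],
    cell_type_boost={"T cell": 3.0},
)
ds, _ = spc.generate_dataset(truth)
spc.volume_normalize(ds)
spc.log_normalize(ds)

# leave-one-animal-out clock evaluation for an abundant cell type
table, m = spc.evaluate_leave_one_animal_out(ds, "Oligodendrocyte")
print(f"R = {m.cell_r:.3f}, MAE = {m.cell_mae:.2f} months, animal r = {m.animal_r:.3f}")

# proximity screen on cross-validated age accelerations
cutoffs = spc.subregion_distance_cutoffs(ds)
preds = spc.cross_validated_predictions(
    ds, ["Oligodendrocyte", "Astrocyte", "Neuron-Excitatory"], n_folds=5
)
accel = spc.age_acceleration(preds)
results, ape, impact = spc.proximity_screen(ds, accel, cutoffs, min_group=30)
print(ape.head(3).round(3))
```

Output:

```
R = 0.997, MAE = 0.60 months, animal r = 1.000
                     ape  n_targets
effector
T cell             0.406          3
Macrophage         0.117          3
Neuron-Excitatory  0.087          3
```

The clock recovers chronological age from smoothed single-cell profiles
almost perfectly on this well-specified simulation (cell-level Pearson
R = 0.997, mean absolute error 0.60 months; per-animal medians correlate
at r = 1.000), and the proximity screen ranks the planted T cell effect
as the most pro-aging effector (APE = +0.41, a Cohen's d averaged over
the three screened target types), well separated from the unplanted
effectors whose APEs hover near zero.

The same pipeline is available from the shell:

```bash
spatialclocks --seed 1 simulate --out sim.h5ad --effector-rule "T cell:+3:30"
spatialclocks preprocess --in sim.h5ad --out clean.h5ad --ledger qc.json
spatialclocks smooth --in clean.h5ad --out smooth.h5ad
spatialclocks train-clocks --in smooth.h5ad --out clocks.json
spatialclocks predict --in smooth.h5ad --clocks clocks.json --out pred.csv
spatialclocks accel --pred pred.csv --out accel.csv
spatialclocks regions --in clean.h5ad --out cutoffs.json
spatialclocks proximity --in smooth.h5ad --accel accel.csv \
    --cutoffs cutoffs.json --out prox.csv
```

plus `permute`, `gradation`, `trajectories`, `aging-genes`, `gnn-train`,
`gnn-perturb`, `loo`, `intervention`, `validate` and `convert`.

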
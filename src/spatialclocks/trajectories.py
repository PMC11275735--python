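"""Gene-expression trajectories over age, archetype clustering, and
aging-gene screens.

A trajectory is the mean expression of one gene, in one cell type and one
subregion, at each profiled age (volume-normalized then total-count-
normalized expression). Trajectories covering fewer than 70% of the ages
are discarded; remaining gaps are filled by last-value-carried-forward
(leading gaps back-filled from the first observed age); rows are
standardized and clustered with k-means (k=9 archetypes).

The aging-gene screen works on per-sample pseudobulk (mean log-normalized
expression per cell type): genes with Spearman rho > 0.3 and a 95%
confidence interval excluding zero from below are "Increasing", mirrored
for "Decreasing". The regional-change statistic compares the oldest and
youngest animals' region-level expression profiles by the mean absolute
log difference over genes, with repeated cell downsampling for comparable
cell numbers.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import interpolate
from scipy.stats import norm, spearmanr
from sklearn.cluster import KMeans

from .data_io import to_dense


@dataclass
class TrajectoryMatrix:
    """Standardized trajectories, rows keyed by (gene, cell_type, subregion)."""

    values: pd.DataFrame       # rows MultiIndex keys, columns ordered ages
    missing_mask: pd.DataFrame  # True where the value was imputed
    dropped_low_coverage: int
    dropped_constant: int

    @property
    def ages(self) -> np.ndarray:
        return self.values.columns.to_numpy(float)


def _totalcount_normalize(X: np.ndarray) -> np.ndarray:
    """Scale every cell to the median of per-cell totals (the conventional
    default target of total-count normalization)."""
    totals = X.sum(axis=1)
    nz = totals > 0
    target = np.median(totals[nz]) if nz.any() else 1.0
    scale = np.where(nz, target / np.where(nz, totals, 1.0), 1.0)
    return X * scale[:, None]


def build_trajectories(
    adata: ad.AnnData,
    coverage: float = 0.7,
    source: str = "volnorm",
) -> TrajectoryMatrix:
    """Build the (gene, cell type, subregion) x age trajectory matrix.

    Expression is the ``source`` layer (volume-normalized counts) after
    total-count normalization. A (cell type, subregion) combination absent
    from more than ``1 - coverage`` of the profiled ages drops all its
    trajectories; gaps in surviving rows are LOCF-imputed. Rows are
    standardized to mean 0, population sd 1 (constant rows dropped).
    """
    ages = np.sort(adata.obs["age_months"].unique().astype(float))
    if len(ages) < 2:
        raise ValueError("need at least 2 distinct ages")
    X = _totalcount_normalize(to_dense(adata.layers[source]))
    key = pd.DataFrame(
        {
            "cell_type": adata.obs["cell_type"].astype(str).to_numpy(),
            "subregion": adata.obs["subregion"].astype(str).to_numpy()
            if "subregion" in adata.obs.columns
            else "all",
            "age": adata.obs["age_months"].to_numpy(float),
        }
    )
    # mean expression per (cell_type, subregion, age), all genes at once
    grouped = key.groupby(["cell_type", "subregion", "age"], sort=True).indices
    combos: dict[tuple[str, str], dict[float, np.ndarray]] = {}
    for (ct, sr, age), idx in grouped.items():
        combos.setdefault((ct, sr), {})[age] = X[idx].mean(axis=0)

    rows, masks, index = [], [], []
    n_low, n_const = 0, 0
    genes = adata.var_names.to_numpy()
    for (ct, sr), by_age in sorted(combos.items()):
        present = np.array([a in by_age for a in ages])
        if present.mean() < coverage:
            n_low += len(genes)
            continue
        mat = np.full((len(genes), len(ages)), np.nan)
        for j, a in enumerate(ages):
            if a in by_age:
                mat[:, j] = by_age[a]
        mask = ~present
        mat = _locf(mat)
        mu = mat.mean(axis=1, keepdims=True)
        sd = mat.std(axis=1, keepdims=True)
        const = (sd.ravel() == 0)
        n_const += int(const.sum())
        std = (mat - mu) / np.where(sd == 0, 1.0, sd)
        for gi in np.flatnonzero(~const):
            rows.append(std[gi])
            masks.append(mask.copy())
            index.append((genes[gi], ct, sr))
    if not rows:
        raise ValueError("no trajectories passed the coverage filter")
    mindex = pd.MultiIndex.from_tuples(index, names=["gene", "cell_type", "subregion"])
    values = pd.DataFrame(np.vstack(rows), index=mindex, columns=ages)
    mask_df = pd.DataFrame(np.vstack(masks), index=mindex, columns=ages)
    return TrajectoryMatrix(
        values=values, missing_mask=mask_df,
        dropped_low_coverage=n_low, dropped_constant=n_const,
    )


def _locf(mat: np.ndarray) -> np.ndarray:
    """Last-value-carried-forward along columns; leading gaps are back-filled
    from the first observed value."""
    out = mat.copy()
    n_rows, n_cols = out.shape
    for j in range(1, n_cols):
        nan = np.isnan(out[:, j])
        out[nan, j] = out[nan, j - 1]
    for j in range(n_cols - 2, -1, -1):  # leading-edge back-fill
        nan = np.isnan(out[:, j])
        out[nan, j] = out[nan, j + 1]
    return out


def cluster_trajectories(
    tm: TrajectoryMatrix | pd.DataFrame, k: int = 9, seed: int = 444
) -> tuple[pd.Series, pd.DataFrame]:
    """K-means archetype clustering of standardized trajectories.

    Returns (cluster id per row, centroid curves). Naming the archetypes
    ("increasing late", "midlife peak", ...) is left to the user.
    """
    values = tm.values if isinstance(tm, TrajectoryMatrix) else tm
    if k > len(values):
        raise ValueError(f"k={k} exceeds the {len(values)} trajectories")
    km = KMeans(n_clusters=k, random_state=seed, n_init="auto")
    ids = km.fit_predict(values.to_numpy())
    centroids = pd.DataFrame(km.cluster_centers_, columns=values.columns)
    return pd.Series(ids, index=values.index, name="cluster"), centroids


def smooth_trajectory(
    ages: np.ndarray, values: np.ndarray, smoothing: float = 20.0, n_dense: int = 200
) -> tuple[np.ndarray, np.ndarray]:
    """Smoothing-spline fit of one trajectory, evaluated on a dense age grid
    (display helper for cluster medians/IQR). ``smoothing=0`` interpolates
    the points exactly."""
    ages = np.asarray(ages, float)
    values = np.asarray(values, float)
    if len(ages) < 4:
        raise ValueError("need at least 4 points for a cubic smoothing spline")
    tck = interpolate.splrep(ages, values, s=smoothing)
    grid = np.linspace(ages[0], ages[-1], n_dense)
    return grid, interpolate.splev(grid, tck)


@dataclass
class AgingGeneCall:
    gene: str
    cell_type: str
    rho: float
    p: float
    ci_low: float
    ci_high: float
    category: str  # Increasing | Decreasing | none


def aging_gene_screen(
    adata: ad.AnnData,
    cell_type: str,
    rho_threshold: float = 0.3,
    layer: str = "lognorm",
) -> pd.DataFrame:
    """Spearman screen of per-sample pseudobulk expression against age.

    The 95% CI uses the Fisher z-transform with SE 1/sqrt(n-3). Genes with
    rho > threshold and CI lower bound > 0 are "Increasing"; rho < -threshold
    and CI upper bound < 0 are "Decreasing".
    """
    mask = (adata.obs["cell_type"].astype(str) == cell_type).to_numpy()
    if not mask.any():
        raise ValueError(f"no cells of type {cell_type!r}")
    X = to_dense(adata.layers[layer])[mask]
    samples = adata.obs["sample_id"].astype(str).to_numpy()[mask]
    age_of = (
        adata.obs.loc[mask, ["sample_id", "age_months"]]
        .astype({"sample_id": str})
        .drop_duplicates("sample_id")
        .set_index("sample_id")["age_months"]
    )
    uniq = pd.unique(samples)
    if len(uniq) < 4:
        raise ValueError("need at least 4 samples for the screen")
    pb = np.vstack([X[samples == s].mean(axis=0) for s in uniq])
    ages = age_of.loc[uniq].to_numpy(float)
    n = len(uniq)
    se = 1.0 / np.sqrt(n - 3)
    zcrit = norm.ppf(0.975)
    records = []
    for j, gene in enumerate(adata.var_names):
        col = pb[:, j]
        if np.all(col == col[0]):
            records.append((gene, cell_type, 0.0, 1.0, 0.0, 0.0, "none"))
            continue
        rho, p = spearmanr(ages, col)
        if np.isnan(rho):
            records.append((gene, cell_type, np.nan, np.nan, np.nan, np.nan, "none"))
            continue
        z = np.arctanh(np.clip(rho, -0.999999, 0.999999))
        lo, hi = np.tanh(z - zcrit * se), np.tanh(z + zcrit * se)
        if rho > rho_threshold and lo > 0:
            cat = "Increasing"
        elif rho < -rho_threshold and hi < 0:
            cat = "Decreasing"
        else:
            cat = "none"
        records.append((gene, cell_type, float(rho), float(p), float(lo), float(hi), cat))
    return pd.DataFrame(
        records, columns=["gene", "cell_type", "rho", "p", "ci_low", "ci_high", "category"]
    )


def regional_change_magnitude(
    adata: ad.AnnData,
    n_young: int = 5,
    n_old: int = 5,
    n_cells_floor: int = 20,
    n_repeats: int = 20,
    seed: int = 0,
    lognorm_target: float = 250.0,
    exclude_regions: tuple[str, ...] = (),
    gene_filter: list[str] | None = None,
) -> pd.DataFrame:
    """Old-minus-young magnitude of regional expression change.

    For each cell type, cells are downsampled (per repeat, without
    replacement) to the minimum count over mouse x region (cell types under
    ``n_cells_floor`` excluded). A mouse x region profile is the mean
    volume-normalized expression renormalized to ``lognorm_target`` and
    log1p-transformed; the statistic per (cell type, region) is the mean
    over genes of |mean old profile - mean young profile|, averaged over
    repeats with a 95% interval.
    """
    obs = adata.obs
    animals = (
        obs[["animal_id", "age_months"]]
        .astype({"animal_id": str})
        .drop_duplicates("animal_id")
        .sort_values("age_months")
    )
    if len(animals) < n_young + n_old:
        raise ValueError("not enough animals")
    young = set(animals["animal_id"].iloc[:n_young])
    old = set(animals["animal_id"].iloc[-n_old:])
    use_animals = young | old

    X = to_dense(adata.layers["volnorm"])
    if gene_filter is not None:
        cols = [adata.var_names.get_loc(g) for g in gene_filter if g in adata.var_names]
        X = X[:, cols]
    ctype = obs["cell_type"].astype(str).to_numpy()
    region = obs["region"].astype(str).to_numpy()
    animal = obs["animal_id"].astype(str).to_numpy()
    in_use = np.isin(animal, list(use_animals)) & ~np.isin(region, exclude_regions)

    rng = np.random.default_rng(seed)
    records = []
    regions = sorted(set(region[in_use]))
    for ct in sorted(set(ctype[in_use])):
        cells = {}
        for a in sorted(use_animals):
            for r in regions:
                idx = np.flatnonzero(in_use & (ctype == ct) & (animal == a) & (region == r))
                cells[(a, r)] = idx
        m = min(len(v) for v in cells.values())
        if m < n_cells_floor:
            continue
        for r in regions:
            stats = []
            for _ in range(n_repeats):
                def profile(group):
                    prof = np.zeros(X.shape[1])
                    for a in group:
                        idx = cells[(a, r)]
                        draw = rng.choice(idx, size=m, replace=False)
                        p = X[draw].mean(axis=0)
                        tot = p.sum()
                        p = np.log1p(p * (lognorm_target / tot)) if tot > 0 else p
                        prof += p
                    return prof / len(group)

                diff = profile(sorted(old)) - profile(sorted(young))
                stats.append(float(np.mean(np.abs(diff))))
            stats = np.asarray(stats)
            records.append(
                {
                    "cell_type": ct,
                    "region": r,
                    "mean_abs_dlog": float(stats.mean()),
                    "ci_low": float(np.quantile(stats, 0.025)),
                    "ci_high": float(np.quantile(stats, 0.975)),
                    "n_cells_per_group": int(m),
                    "n_repeats": n_repeats,
                }
            )
    return pd.DataFrame.from_records(records)
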
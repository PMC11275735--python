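"""Directional effector->target cell proximity effects on age acceleration.

For an (effector, target) pair of cell types, target cells closer to an
effector than the subregion-specific distance cutoff are labeled "Near" and
matched 1:1, within each (sample, subregion) stratum, to "Far" target cells
beyond the cutoff — by default the cells farthest from the effector type,
alternatively a seeded random draw or a greedy match on total raw
transcript counts. The proximity effect is Cohen's d of age acceleration,
Near minus Far (pooled-sd form), with pairs below 50 Near or 50 Far cells
filtered out. The average proximity effect (APE) of an effector is the
mean d over its surviving targets.

Controls and variants: spatial permutation nulls (coordinates permuted
within each sample), area-restricted annuli (inner radius 15 um below the
outer) against segmentation spillover, distance-gradation profiles, and
signature-based subtype splits for activation/inflammation glia.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial import cKDTree
from scipy.stats import levene, ttest_ind

from .regions import SubregionCutoffs

#: Activation / inflammation glia signatures (genes shared with the panel).
MICROGLIA_ACTIVATION_GENES = (
    "Apoe", "B2m", "C1qa", "Cd69", "Cd9", "Il1a", "Il1b", "Il6", "Lyz2",
)
OLIGO_INFLAMMATION_GENES = ("C4b", "Cdkn1a", "H2-D1", "Ifit1", "Stat1")


def nearest_effector_distance(
    adata: ad.AnnData, effector_type: str
) -> np.ndarray:
    """Per cell, the shortest Euclidean distance to any effector cell in the
    same section; an effector cell never counts itself (a section with a
    single effector gives +inf for that cell)."""
    ctype = adata.obs["cell_type"].astype(str).to_numpy()
    samples = adata.obs["sample_id"].astype(str).to_numpy()
    xy = np.column_stack(
        [adata.obs["x"].to_numpy(float), adata.obs["y"].to_numpy(float)]
    )
    out = np.full(adata.n_obs, np.inf)
    is_eff = ctype == effector_type
    for s in pd.unique(samples):
        sel = samples == s
        eff = sel & is_eff
        n_eff = int(eff.sum())
        if n_eff == 0:
            continue
        tree = cKDTree(xy[eff])
        others = sel & ~is_eff
        if others.any():
            out[others], _ = tree.query(xy[others], k=1)
        self_cells = sel & is_eff
        if n_eff >= 2:
            d2, _ = tree.query(xy[self_cells], k=2)
            out[self_cells] = d2[:, 1]
    return out


@dataclass
class NearFarLabels:
    """Per-target-cell Near/Far assignment for one (effector, target) pair."""

    effector: str
    target: str
    table: pd.DataFrame  # index cell_id; distance, sample_id, subregion, label
    strategy: str
    dropped_strata: list[tuple] = field(default_factory=list)

    @property
    def n_near(self) -> int:
        return int((self.table["label"] == "Near").sum())

    @property
    def n_far(self) -> int:
        return int((self.table["label"] == "Far").sum())

    @property
    def n_targets(self) -> int:
        return len(self.table)


def label_near_far(
    adata: ad.AnnData,
    effector: str,
    target: str,
    cutoffs: SubregionCutoffs | dict,
    strategy: str = "farthest",
    cutoff_scale: float = 1.0,
    area_restricted: bool = False,
    inner_offset_um: float = 15.0,
    seed: int = 0,
    distances: np.ndarray | None = None,
) -> NearFarLabels:
    """Label Near/Far target cells, stratified by (sample, subregion).

    Near: nearest-effector distance strictly below the subregion cutoff
    (times ``cutoff_scale``); in area-restricted mode, strictly inside the
    annulus (outer - inner_offset_um, outer). Far cells are drawn 1:1 per
    stratum from targets strictly beyond the outer cutoff by the chosen
    strategy: ``farthest`` (largest distances), ``random`` (seeded uniform),
    or ``count_matched`` (greedy, total raw counts closest to the Near
    mean). Strata with Near cells but an empty Far pool are dropped and
    recorded.
    """
    cut_map = cutoffs.cutoffs if isinstance(cutoffs, SubregionCutoffs) else dict(cutoffs)
    if distances is None:
        distances = nearest_effector_distance(adata, effector)
    ctype = adata.obs["cell_type"].astype(str).to_numpy()
    t_mask = ctype == target
    sub_col = (
        adata.obs["subregion"].astype(str).to_numpy()
        if "subregion" in adata.obs.columns
        else np.full(adata.n_obs, "all")
    )
    df = pd.DataFrame(
        {
            "distance": distances[t_mask],
            "sample_id": adata.obs["sample_id"].astype(str).to_numpy()[t_mask],
            "subregion": sub_col[t_mask],
        },
        index=adata.obs_names[t_mask],
    )
    missing = set(df["subregion"]) - set(cut_map)
    if missing:
        raise ValueError(f"no distance cutoff for subregions: {sorted(missing)}")
    if strategy == "count_matched":
        X = adata.X
        totals = (
            np.asarray(X.sum(axis=1)).ravel() if sp.issparse(X) else np.asarray(X).sum(axis=1)
        ).astype(float)
        df["total_counts"] = totals[t_mask]

    rng = np.random.default_rng(seed)
    labels_arr = np.full(len(df), "unlabeled", dtype=object)
    dropped: list[tuple] = []
    # positional index for deterministic tie-breaking by cell order
    df["_pos"] = np.arange(len(df))
    for (samp, subr), grp in df.groupby(["sample_id", "subregion"], sort=True):
        outer = cut_map[subr] * cutoff_scale
        d = grp["distance"].to_numpy()
        if area_restricted:
            inner = outer - inner_offset_um
            near_mask = (d > inner) & (d < outer)
        else:
            near_mask = d < outer
        n_near = int(near_mask.sum())
        if n_near == 0:
            continue
        far_pool = np.flatnonzero((d > outer) & np.isfinite(d))
        if len(far_pool) == 0:
            dropped.append((samp, subr))
            continue
        n_far = min(n_near, len(far_pool))
        if strategy == "farthest":
            order = np.lexsort((grp["_pos"].to_numpy()[far_pool], -d[far_pool]))
            chosen = far_pool[order[:n_far]]
        elif strategy == "random":
            chosen = rng.choice(far_pool, size=n_far, replace=False)
        elif strategy == "count_matched":
            target_mean = grp["total_counts"].to_numpy()[near_mask].mean()
            gap = np.abs(grp["total_counts"].to_numpy()[far_pool] - target_mean)
            order = np.lexsort((grp["_pos"].to_numpy()[far_pool], gap))
            chosen = far_pool[order[:n_far]]
        else:
            raise ValueError(f"unknown strategy {strategy!r}")
        pos = grp["_pos"].to_numpy()
        labels_arr[pos[near_mask]] = "Near"
        labels_arr[pos[chosen]] = "Far"
    df["label"] = labels_arr
    df = df.drop(columns="_pos")
    return NearFarLabels(
        effector=effector, target=target, table=df, strategy=strategy, dropped_strata=dropped
    )


@dataclass
class ProximityResult:
    """One (effector, target) proximity-effect record."""

    effector: str
    target: str
    d: float                  # Cohen's d of age acceleration, Near - Far
    t: float
    p: float
    n_near: int
    n_far: int
    normalized_frequency: float  # n_near / total target cells
    passes_filter: bool
    degenerate: bool = False  # zero pooled variance


def cohens_d(near: np.ndarray, far: np.ndarray) -> float:
    """Two-sample Cohen's d with pooled sd (per-group ddof=1)."""
    n1, n2 = len(near), len(far)
    s1 = np.var(near, ddof=1) if n1 > 1 else 0.0
    s2 = np.var(far, ddof=1) if n2 > 1 else 0.0
    denom_df = n1 + n2 - 2
    if denom_df <= 0:
        return np.nan
    pooled = np.sqrt(((n1 - 1) * s1 + (n2 - 1) * s2) / denom_df)
    if pooled == 0:
        return np.nan
    return float((np.mean(near) - np.mean(far)) / pooled)


def proximity_effect(
    labels: NearFarLabels,
    accel: pd.DataFrame,
    min_group: int = 50,
    welch: bool = False,
    value_col: str = "age_acceleration",
) -> ProximityResult:
    """Cohen's d and t-test of age acceleration, Near vs matched Far cells.

    ``accel`` is the per-cell prediction table (indexed by cell id) carrying
    ``value_col``. Pairs with fewer than ``min_group`` Near or Far cells are
    flagged as failing the filter.
    """
    tab = labels.table.join(accel[[value_col]], how="inner")
    near = tab.loc[tab["label"] == "Near", value_col].to_numpy(float)
    far = tab.loc[tab["label"] == "Far", value_col].to_numpy(float)
    d = cohens_d(near, far) if len(near) and len(far) else np.nan
    degenerate = bool(len(near) and len(far) and np.isnan(d))
    if len(near) > 1 and len(far) > 1 and not degenerate:
        t_res = ttest_ind(near, far, equal_var=not welch)
        t_stat, p = float(t_res.statistic), float(t_res.pvalue)
    else:
        t_stat, p = np.nan, np.nan
    return ProximityResult(
        effector=labels.effector,
        target=labels.target,
        d=d,
        t=t_stat,
        p=p,
        n_near=len(near),
        n_far=len(far),
        normalized_frequency=len(near) / labels.n_targets if labels.n_targets else np.nan,
        passes_filter=len(near) >= min_group and len(far) >= min_group,
        degenerate=degenerate,
    )


def proximity_screen(
    adata: ad.AnnData,
    accel: pd.DataFrame,
    cutoffs: SubregionCutoffs | dict,
    effectors: list[str] | None = None,
    targets: list[str] | None = None,
    min_group: int = 50,
    strategy: str = "farthest",
    cutoff_scale: float = 1.0,
    area_restricted: bool = False,
    inner_offset_um: float = 15.0,
    region: str | None = None,
    condition: str | None = None,
    seed: int = 0,
    welch: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """All-pairs proximity screen.

    Returns ``(results, ape, target_impact)``: the per-pair table (with
    ``passes_filter``), the per-effector average proximity effect (mean d
    over surviving targets), and the per-target mean absolute effect.
    Optional ``region`` / ``condition`` restrict both cells and
    accelerations before anything is computed.
    """
    work = adata
    if region is not None:
        work = work[(work.obs["region"].astype(str) == region).to_numpy()]
    if condition is not None:
        work = work[(work.obs["condition"].astype(str) == condition).to_numpy()]
    acc = accel[accel.index.isin(work.obs_names)]
    types_present = work.obs["cell_type"].astype(str).unique().tolist()
    effectors = effectors or types_present
    targets = targets or sorted(acc["cell_type"].astype(str).unique().tolist())

    records = []
    for eff in effectors:
        if eff not in types_present:
            continue
        dist = nearest_effector_distance(work, eff)
        for tgt in targets:
            labels = label_near_far(
                work, eff, tgt, cutoffs,
                strategy=strategy, cutoff_scale=cutoff_scale,
                area_restricted=area_restricted, inner_offset_um=inner_offset_um,
                seed=seed, distances=dist,
            )
            res = proximity_effect(labels, acc, min_group=min_group, welch=welch)
            records.append(vars(res))
    results = pd.DataFrame.from_records(records)
    if results.empty:
        return results, pd.DataFrame(), pd.DataFrame()
    surviving = results[results["passes_filter"] & results["d"].notna()]
    ape = (
        surviving.groupby("effector")["d"]
        .agg(ape="mean", n_targets="size")
        .sort_values("ape", ascending=False)
    )
    impact = (
        surviving.assign(abs_d=surviving["d"].abs())
        .groupby("target")["abs_d"]
        .agg(mean_abs_d="mean", n_effectors="size")
        .sort_values("mean_abs_d", ascending=False)
    )
    return results, ape, impact


@dataclass
class PermutationNull:
    """APE distribution of each effector under spatial permutation."""

    ape_per_perm: pd.DataFrame  # rows permutations, columns effectors
    seeds: list[int]
    master_seed: int

    def summary(self) -> pd.DataFrame:
        med = self.ape_per_perm.median()
        lo = self.ape_per_perm.quantile(0.025)
        hi = self.ape_per_perm.quantile(0.975)
        return pd.DataFrame({"median": med, "ci_low": lo, "ci_high": hi})


def spatial_permutation_null(
    adata: ad.AnnData,
    accel: pd.DataFrame,
    cutoffs: SubregionCutoffs | dict,
    n_perm: int = 20,
    master_seed: int = 444,
    **screen_kwargs,
) -> PermutationNull:
    """Negative control: permute cell coordinates within each sample
    (equivalent to shuffling cell-type labels) and rerun the screen.

    Permutation seeds are drawn uniformly from [0, 50000] under the master
    seed, so the whole null is reproducible from ``master_seed``.
    """
    master = np.random.default_rng(master_seed)
    seeds = [int(s) for s in master.integers(0, 50001, size=n_perm)]
    samples = adata.obs["sample_id"].astype(str).to_numpy()
    xy = np.column_stack(
        [adata.obs["x"].to_numpy(float), adata.obs["y"].to_numpy(float)]
    )
    rows = []
    for s in seeds:
        rng = np.random.default_rng(s)
        perm_xy = xy.copy()
        for samp in pd.unique(samples):
            sel = np.flatnonzero(samples == samp)
            perm_xy[sel] = perm_xy[sel[rng.permutation(len(sel))]]
        # the screen only reads obs (positions, types, strata) and, for the
        # count-matched strategy, X totals — share X instead of copying
        # every expression layer
        perm_obs = adata.obs.copy()
        perm_obs["x"] = perm_xy[:, 0]
        perm_obs["y"] = perm_xy[:, 1]
        perm = ad.AnnData(X=adata.X, obs=perm_obs)
        _, ape, _ = proximity_screen(perm, accel, cutoffs, **screen_kwargs)
        rows.append(ape["ape"] if "ape" in ape else pd.Series(dtype=float))
    table = pd.DataFrame(rows).reset_index(drop=True)
    return PermutationNull(ape_per_perm=table, seeds=seeds, master_seed=master_seed)


def gradation_profile(
    adata: ad.AnnData,
    accel: pd.DataFrame,
    cutoffs: SubregionCutoffs | dict,
    unit_distances: list[float],
    area_restricted: bool = False,
    inner_offset_um: float = 15.0,
    **screen_kwargs,
) -> pd.DataFrame:
    """Proximity effect as a function of distance: cutoffs are scaled by
    each unit distance u (area-restricted mode: outer = u * cutoff,
    inner = outer - 15 um) and the screen recomputed. Returns the stacked
    per-pair results with a ``unit_distance`` column."""
    units = list(unit_distances)
    if not units or any(u <= 0 for u in units) or sorted(units) != units:
        raise ValueError("unit_distances must be positive and increasing")
    frames = []
    for u in units:
        results, _, _ = proximity_screen(
            adata, accel, cutoffs,
            cutoff_scale=u, area_restricted=area_restricted,
            inner_offset_um=inner_offset_um, **screen_kwargs,
        )
        results["unit_distance"] = u
        frames.append(results)
    return pd.concat(frames, ignore_index=True)


def signature_score(
    adata: ad.AnnData, gene_list: list[str], layer: str = "lognorm"
) -> np.ndarray:
    """Per-cell signature score: sum of log-normalized expression over the
    listed genes that are present in the panel."""
    present = [g for g in gene_list if g in adata.var_names]
    if not present:
        raise ValueError("no signature genes present in the panel")
    from .data_io import to_dense

    X = to_dense(adata.layers[layer])
    cols = [adata.var_names.get_loc(g) for g in present]
    return X[:, cols].sum(axis=1)


def subtype_split(scores: np.ndarray, top_fraction: float = 0.002) -> np.ndarray:
    """Boolean mask of the top ``top_fraction`` of cells by score (ties
    broken by cell index so exactly floor(n * f) cells are selected)."""
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    scores = np.asarray(scores, float)
    n = len(scores)
    k = int(np.floor(n * top_fraction))
    mask = np.zeros(n, dtype=bool)
    if k == 0:
        return mask
    order = np.lexsort((np.arange(n), -scores))
    mask[order[:k]] = True
    return mask


def levene_equal_variance(*groups) -> tuple[float, float]:
    """Brown-Forsythe (median-centered) Levene test with 5% trimming, the
    diagnostic backing the use of Cohen's d / Student's t between Near and
    Far groups."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if len(np.asarray(g)) < 2:
            raise ValueError("each group needs n >= 2")
    stat, p = levene(*groups, center="median", proportiontocut=0.05)
    return float(stat), float(p)
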
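"""Subregion annotation and Delaunay-based neighbour-distance cutoffs.

Subregions are annotated from the cell-type composition of each cell's
local neighbourhood (counts of every type within a 100 um radius, PCA,
k-means with k=25), with the merging of clusters into named subregions left
to an explicit user mapping. The proximity analysis' per-subregion distance
cutoffs are the across-sample mean of the median Delaunay neighbour-to-
neighbour distance within each subregion.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError, cKDTree
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA


def neighborhood_composition_clusters(
    adata: ad.AnnData,
    radius: float = 100.0,
    k: int = 25,
    n_pcs: int | float = 0.95,
    seed: int = 0,
) -> np.ndarray:
    """Cluster cells by the cell-type composition of their 100 um
    neighbourhood (same section only).

    ``n_pcs`` may be an int (component count) or a float in (0, 1)
    (variance fraction to retain, default 95%). Returns one cluster id per
    cell; naming/merging clusters into subregions is a user-supplied
    mapping.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    types = adata.obs["cell_type"].astype(str).to_numpy()
    vocab = pd.unique(types)
    t_idx = pd.Categorical(types, categories=vocab).codes
    samples = adata.obs["sample_id"].astype(str).to_numpy()
    xy = np.column_stack(
        [adata.obs["x"].to_numpy(float), adata.obs["y"].to_numpy(float)]
    )
    comp = np.zeros((adata.n_obs, len(vocab)))
    for s in pd.unique(samples):
        sel = np.flatnonzero(samples == s)
        tree = cKDTree(xy[sel])
        neighbors = tree.query_ball_point(xy[sel], r=radius)
        for row, neigh in zip(sel, neighbors):
            np.add.at(comp[row], t_idx[sel[np.asarray(neigh, int)]], 1)
    n_comp = n_pcs if isinstance(n_pcs, int) else min(float(n_pcs), 0.9999)
    n_comp = min(n_comp, min(comp.shape) - 1) if isinstance(n_comp, int) else n_comp
    pcs = PCA(n_components=n_comp, random_state=seed).fit_transform(comp)
    km = KMeans(n_clusters=min(k, adata.n_obs), random_state=seed, n_init="auto")
    return km.fit_predict(pcs)


def delaunay_neighbor_distances(
    adata: ad.AnnData, sample_id: str, jitter: float = 0.0, seed: int = 0
) -> dict[str, np.ndarray]:
    """Delaunay edge lengths per subregion for one section.

    Each edge is assigned to the subregion of both endpoints (an edge
    crossing two subregions contributes to both). Degenerate geometry
    raises with a hint to pass ``jitter`` (um of coordinate noise).
    """
    sel = (adata.obs["sample_id"].astype(str) == sample_id).to_numpy()
    if sel.sum() < 3:
        raise ValueError(f"section {sample_id!r} has fewer than 3 cells")
    xy = np.column_stack(
        [adata.obs["x"].to_numpy(float)[sel], adata.obs["y"].to_numpy(float)[sel]]
    )
    if jitter > 0:
        xy = xy + np.random.default_rng(seed).normal(0, jitter, xy.shape)
    try:
        tri = Delaunay(xy)
    except QhullError as exc:
        raise ValueError(
            f"degenerate geometry in section {sample_id!r} (collinear cells?); "
            "retry with jitter > 0"
        ) from exc
    edges = set()
    for simplex in tri.simplices:
        for a in range(3):
            i, j = int(simplex[a]), int(simplex[(a + 1) % 3])
            edges.add((min(i, j), max(i, j)))
    edges = np.array(sorted(edges))
    lengths = np.linalg.norm(xy[edges[:, 0]] - xy[edges[:, 1]], axis=1)
    if "subregion" in adata.obs.columns:
        sub = adata.obs["subregion"].astype(str).to_numpy()[sel]
    else:
        sub = np.full(sel.sum(), "all")
    out: dict[str, list] = {}
    for (i, j), ln in zip(edges, lengths):
        for s in {sub[i], sub[j]}:
            out.setdefault(s, []).append(ln)
    return {s: np.asarray(v) for s, v in out.items()}


@dataclass
class SubregionCutoffs:
    """Per-subregion Near-distance cutoffs (um) with per-sample provenance."""

    cutoffs: dict[str, float]
    per_sample_medians: pd.DataFrame  # rows sample, columns subregion

    def __getitem__(self, subregion: str) -> float:
        return self.cutoffs[subregion]


def subregion_distance_cutoffs(adata: ad.AnnData, jitter: float = 0.0) -> SubregionCutoffs:
    """Per subregion: median Delaunay edge length per sample, then the mean
    of those medians across the samples where the subregion occurs."""
    samples = pd.unique(adata.obs["sample_id"].astype(str))
    rows = {}
    for s in samples:
        dists = delaunay_neighbor_distances(adata, s, jitter=jitter)
        rows[s] = {sub: float(np.median(v)) for sub, v in dists.items()}
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index(axis=1)
    cutoffs = {sub: float(table[sub].dropna().mean()) for sub in table.columns}
    return SubregionCutoffs(cutoffs=cutoffs, per_sample_medians=table)
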
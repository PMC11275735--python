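"""SpatialSmooth: graph propagation of expression over same-type neighbours.

For one cell type, each cell is linked to its k nearest neighbours of the
same type (Euclidean distance, within the same tissue section), giving a
directed k-NN adjacency whose L1 row normalization is the propagation
matrix S. Expression is then smoothed by iterating

    X_{t+1} = (1 - alpha) * X + alpha * S @ X_t

from X_0 = X until the sup-norm change drops below a tolerance or an
iteration cap is reached. For alpha < 1 the map is a contraction with fixed
point X* = (1 - alpha) (I - alpha S)^{-1} X, which
:func:`smooth_closed_form` computes directly as a dense-solve oracle.

Isolated cells (a section with a single cell of the type) receive a unit
self-loop so S stays row-stochastic and the fixed point returns the cell's
own value.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree

from .config import SmoothingConfig
from .data_io import to_dense


@dataclass
class CellTypeGraph:
    """Per-cell-type spatial k-NN graph (possibly spanning several sections).

    ``cell_index`` are integer positions into the parent dataset, and ``S``
    is the row-stochastic propagation matrix in that order. Edges never
    cross sections.
    """

    cell_type: str
    cell_index: np.ndarray        # positions into the parent AnnData
    S: sp.csr_matrix              # L1-row-normalized adjacency
    k: int

    @property
    def n_cells(self) -> int:
        return len(self.cell_index)


def _section_knn(xy: np.ndarray, k: int) -> sp.csr_matrix:
    """Directed k-NN adjacency (row-normalized) for one section; the single
    cell of a section gets a self-loop."""
    n = len(xy)
    if n == 1:
        return sp.csr_matrix(np.array([[1.0]]))
    k_eff = min(k, n - 1)
    tree = cKDTree(xy)
    _, idx = tree.query(xy, k=k_eff + 1)
    idx = np.atleast_2d(idx)
    ii = np.repeat(np.arange(n), k_eff + 1)
    jj = idx.ravel()
    keep = ii != jj
    # coincident points: a row may lack its own index among the k+1 hits;
    # drop that row's last (farthest) hit to keep exactly k_eff neighbours
    has_self = np.zeros(n, dtype=bool)
    has_self[ii[~keep]] = True
    if not has_self.all():
        last = np.zeros((n, k_eff + 1), dtype=bool)
        last[~has_self, -1] = True
        keep &= ~last.ravel()
    A = sp.csr_matrix(
        (np.ones(keep.sum()), (ii[keep], jj[keep])), shape=(n, n)
    )
    inv = 1.0 / np.asarray(A.sum(axis=1)).ravel()
    return sp.diags(inv) @ A


def build_same_type_knn(
    adata: ad.AnnData, cell_type: str, k: int = 20
) -> CellTypeGraph:
    """Build the same-type spatial k-NN graph for one cell type.

    Each section (``sample_id``) contributes an independent block: cells are
    linked to their min(k, n-1) nearest same-type cells in that section.
    """
    mask = (adata.obs["cell_type"].astype(str) == cell_type).to_numpy()
    if not mask.any():
        raise ValueError(f"unknown or absent cell type {cell_type!r}")
    index = np.flatnonzero(mask)
    samples = adata.obs["sample_id"].astype(str).to_numpy()[index]
    xy = np.column_stack(
        [adata.obs["x"].to_numpy(float)[index], adata.obs["y"].to_numpy(float)[index]]
    )
    blocks = []
    order = []
    for s in dict.fromkeys(samples):  # preserves first-appearance order
        sel = np.flatnonzero(samples == s)
        order.append(sel)
        blocks.append(_section_knn(xy[sel], k))
    perm = np.concatenate(order)
    S_perm = sp.block_diag(blocks, format="csr")
    # un-permute back to dataset order of the type's cells
    inv = np.empty_like(perm)
    inv[perm] = np.arange(len(perm))
    P = sp.csr_matrix(
        (np.ones(len(perm)), (np.arange(len(perm)), perm)), shape=(len(perm),) * 2
    )
    S = (P.T @ S_perm @ P).tocsr()
    return CellTypeGraph(cell_type=cell_type, cell_index=index, S=S, k=k)


def smooth(
    X: np.ndarray, graph: CellTypeGraph, cfg: SmoothingConfig | None = None
) -> tuple[np.ndarray, int, bool]:
    """Iterate the smoothing update on ``X`` (rows aligned with the graph).

    Returns ``(X_T, iterations_used, converged)``; convergence means the
    sup-norm change fell below ``cfg.tol``.
    """
    cfg = cfg or SmoothingConfig()
    X = np.asarray(X, dtype=np.float64)
    if X.shape[0] != graph.n_cells:
        raise ValueError(f"X has {X.shape[0]} rows for a {graph.n_cells}-cell graph")
    if cfg.alpha == 0:
        return X.copy(), 1, True
    Xt = X.copy()
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        Xn = (1.0 - cfg.alpha) * X + cfg.alpha * (graph.S @ Xt)
        delta = np.max(np.abs(Xn - Xt)) if Xn.size else 0.0
        Xt = Xn
        if delta < cfg.tol:
            converged = True
            break
    return Xt, it, converged


def smooth_closed_form(
    X: np.ndarray, graph: CellTypeGraph, alpha: float = 0.8
) -> np.ndarray:
    """Fixed point of the smoothing iteration by dense linear solve:
    ``(I - alpha S) X* = (1 - alpha) X``. Intended as an oracle for graphs
    up to a few thousand cells."""
    if alpha >= 1:
        raise ValueError("closed form requires alpha < 1")
    if alpha == 0:
        return np.array(X, dtype=np.float64, copy=True)
    n = graph.n_cells
    A = np.eye(n) - alpha * graph.S.toarray()
    return np.linalg.solve(A, (1.0 - alpha) * np.asarray(X, dtype=np.float64))


def smooth_dataset(
    adata: ad.AnnData,
    cfg: SmoothingConfig | None = None,
    source: str = "lognorm",
    layer_out: str = "smoothed",
    cell_types: list[str] | None = None,
) -> dict[str, dict]:
    """Smooth the ``source`` layer per cell type and write ``layer_out``.

    Cells of types not listed keep their unsmoothed values. Returns a
    per-type convergence log ``{type: {iterations, converged, n_cells}}``.
    """
    cfg = cfg or SmoothingConfig()
    X = to_dense(adata.layers[source])
    out = X.copy()
    log: dict[str, dict] = {}
    types = cell_types or adata.obs["cell_type"].astype(str).unique().tolist()
    for ctype in types:
        g = build_same_type_knn(adata, ctype, cfg.k_neighbors)
        sm, iters, conv = smooth(X[g.cell_index], g, cfg)
        out[g.cell_index] = sm
        log[ctype] = {"iterations": iters, "converged": bool(conv), "n_cells": g.n_cells}
    adata.layers[layer_out] = out
    return log
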
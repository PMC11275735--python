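"""QC filtering and normalization of raw MERFISH counts.

The QC rules, in application order:

1. doublets: ``doublet_score >= doublet_cutoff`` (only when scores present);
2. segmentation volume ``<= min_volume`` or ``>= max_volume_factor x median``
   (median taken over cells surviving rule 1);
3. total counts ``<= min_counts``;
4. expressed genes ``<= min_genes``;
5. after pooling all sections: cells in the top and bottom
   ``total_expr_trim`` tails of total expression.

The trim quantile bounds of rule 5 are computed on the data seen by the
call unless explicit bounds are supplied in the thresholds, and the bounds
used are always recorded in the returned ledger; re-applying the filter with
those recorded bounds is a no-op.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import anndata as ad
import numpy as np
import scipy.sparse as sp

from .data_io import to_dense


@dataclass
class QCThresholds:
    min_volume: float = 100.0          # um^3, exclusive
    max_volume_factor: float = 3.0     # x median volume, exclusive
    min_counts: int = 20               # exclusive
    min_genes: int = 5                 # exclusive
    total_expr_trim: float = 0.02      # each tail, after pooling sections
    doublet_cutoff: float | None = 0.18
    lognorm_target: float = 250.0
    scale_clip: float = 10.0
    trim_on_volnorm: bool = False      # trim on volume-normalized totals instead of raw
    trim_bounds: tuple[float, float] | None = None  # explicit (low, high) totals

    def __post_init__(self) -> None:
        if not 0 <= self.total_expr_trim < 0.5:
            raise ValueError("total_expr_trim must be in [0, 0.5)")
        if self.min_volume <= 0 or self.max_volume_factor <= 0:
            raise ValueError("volume thresholds must be positive")


def _row_totals(adata: ad.AnnData) -> np.ndarray:
    X = adata.X
    if sp.issparse(X):
        return np.asarray(X.sum(axis=1)).ravel().astype(float)
    return np.asarray(X, dtype=float).sum(axis=1)


def _genes_detected(adata: ad.AnnData) -> np.ndarray:
    X = adata.X
    if sp.issparse(X):
        return np.asarray((X > 0).sum(axis=1)).ravel()
    return (np.asarray(X) > 0).sum(axis=1)


def qc_filter(
    adata: ad.AnnData, thr: QCThresholds | None = None
) -> tuple[ad.AnnData, dict]:
    """Apply the QC rules in order; return the filtered dataset and a ledger.

    The ledger maps rule name -> number of cells removed by that rule (in
    application order) and records the trim bounds actually used.
    """
    thr = thr or QCThresholds()
    keep = np.ones(adata.n_obs, dtype=bool)
    ledger: dict = {}

    if thr.doublet_cutoff is not None and "doublet_score" in adata.obs.columns:
        scores = adata.obs["doublet_score"].to_numpy(float)
        rm = keep & (scores >= thr.doublet_cutoff)
        ledger["doublet"] = int(rm.sum())
        keep &= ~rm
    else:
        ledger["doublet"] = 0

    vol = adata.obs["volume"].to_numpy(float)
    med = np.median(vol[keep]) if keep.any() else np.nan
    rm = keep & ((vol <= thr.min_volume) | (vol >= thr.max_volume_factor * med))
    ledger["volume"] = int(rm.sum())
    keep &= ~rm

    totals = _row_totals(adata)
    rm = keep & (totals <= thr.min_counts)
    ledger["min_counts"] = int(rm.sum())
    keep &= ~rm

    ngenes = _genes_detected(adata)
    rm = keep & (ngenes <= thr.min_genes)
    ledger["min_genes"] = int(rm.sum())
    keep &= ~rm

    trim_vals = totals / vol if thr.trim_on_volnorm else totals
    if thr.trim_bounds is not None:
        lo, hi = thr.trim_bounds
    elif keep.any() and thr.total_expr_trim > 0:
        lo, hi = np.quantile(
            trim_vals[keep], [thr.total_expr_trim, 1.0 - thr.total_expr_trim]
        )
    else:
        lo, hi = -np.inf, np.inf
    rm = keep & ((trim_vals < lo) | (trim_vals > hi))
    ledger["total_expr_trim"] = int(rm.sum())
    ledger["trim_bounds"] = (float(lo), float(hi))
    keep &= ~rm

    if not keep.any():
        raise ValueError("all cells removed by QC filtering")
    out = adata[keep].copy()
    ledger["n_kept"] = int(keep.sum())
    return out, ledger


def volume_normalize(adata: ad.AnnData, layer_out: str = "volnorm") -> ad.AnnData:
    """Divide each cell's raw counts by its segmentation volume."""
    vol = adata.obs["volume"].to_numpy(float)
    bad = ~(vol > 0)
    if bad.any():
        raise ValueError(
            f"zero/negative volume for cells: {adata.obs_names[bad].tolist()[:10]}"
        )
    X = to_dense(adata.X)
    adata.layers[layer_out] = X / vol[:, None]
    return adata


def log_normalize(
    adata: ad.AnnData,
    target: float = 250.0,
    source: str | None = None,
    layer_out: str = "lognorm",
) -> ad.AnnData:
    """Scale each cell's expression to sum to ``target``, then take ln(1 + v).

    ``source=None`` uses raw counts; any layer name may be given instead.
    All-zero cells are left all-zero and recorded in
    ``uns['lognorm_zero_cells']`` with a warning.
    """
    X = to_dense(adata.X if source is None else adata.layers[source])
    totals = X.sum(axis=1)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} all-zero cells left unnormalized", stacklevel=2
        )
        adata.uns["lognorm_zero_cells"] = adata.obs_names[zero].tolist()
    scale = np.where(zero, 1.0, target / np.where(zero, 1.0, totals))
    adata.layers[layer_out] = np.log1p(X * scale[:, None])
    return adata


def scale_z(
    adata: ad.AnnData,
    clip: float = 10.0,
    source: str = "lognorm",
    layer_out: str = "scaled",
) -> ad.AnnData:
    """Per-gene z-score (population sd) of the log-normalized layer, with
    values truncated at ``clip`` after scaling; zero-variance genes map to 0."""
    X = to_dense(adata.layers[source])
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # ddof=0
    safe_sd = np.where(sd == 0, 1.0, sd)
    Z = (X - mean) / safe_sd
    Z[:, sd == 0] = 0.0
    adata.layers[layer_out] = np.minimum(Z, clip)
    return adata
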
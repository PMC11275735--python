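"""Data model and I/O for spatial single-cell datasets.

A dataset is an :class:`anndata.AnnData` with the following conventions:

* ``X`` holds raw transcript counts (cells x genes, non-negative integers,
  dense or sparse);
* ``layers`` hold derived matrices of identical shape, by convention
  ``"volnorm"``, ``"lognorm"``, ``"scaled"``, ``"smoothed"``;
* ``obs`` carries per-cell metadata: ``x``, ``y`` (centroid, microns),
  ``volume`` (segmentation volume, cubic microns), ``cell_type``,
  ``animal_id``, ``sample_id`` (one tissue section), ``age_months``, and
  optionally ``region``, ``subregion``, ``condition``, ``doublet_score``,
  ``effective_age`` (synthetic ground truth);
* ``obs_names`` are unique cell ids, ``var_names`` unique gene names.

Coordinates are continuous microns in a per-section frame; distances are
never computed across different ``sample_id`` values.

Supported on-disk formats: h5ad, MatrixMarket (``.mtx`` plus ``genes.tsv``
and ``cells.tsv`` sidecars, written to a directory), and delimited text
(``matrix.csv`` / ``genes.csv`` / ``cells.csv`` in a directory).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

#: The 18 cell type annotations of the mouse brain MERFISH panel; used as the
#: default vocabulary by the synthetic generator and for GNN one-hot encoding.
#: The cell-type vocabulary of real datasets is open (any strings).
CELL_TYPES: tuple[str, ...] = (
    "Neuron-Excitatory",
    "Neuron-Inhibitory",
    "Neuron-MSN",
    "Astrocyte",
    "Oligodendrocyte",
    "OPC",
    "Microglia",
    "Endothelial",
    "Pericyte",
    "VSMC",
    "VLMC",
    "Ependymal",
    "NSC",
    "Neuroblast",
    "Macrophage",
    "T cell",
    "B cell",
    "Neutrophil",
)

REQUIRED_OBS = ("x", "y", "cell_type", "animal_id", "age_months")
NUMERIC_OBS = ("x", "y", "volume", "age_months", "doublet_score")
CATEGORICAL_OBS = ("cell_type", "animal_id", "sample_id", "region", "subregion", "condition")


class SchemaError(ValueError):
    """Raised when a dataset is missing required structure."""


def make_dataset(
    counts,
    gene_names,
    obs: pd.DataFrame,
    layers: dict | None = None,
) -> ad.AnnData:
    """Assemble a validated dataset from a count matrix and metadata table.

    ``obs`` must contain the required columns (:data:`REQUIRED_OBS`); its
    index provides the cell ids. ``sample_id`` defaults to ``animal_id``
    when absent (one section per animal).
    """
    obs = obs.copy()
    for col in REQUIRED_OBS:
        if col not in obs.columns:
            raise SchemaError(f"missing required column: {col!r}")
    if "sample_id" not in obs.columns:
        obs["sample_id"] = obs["animal_id"]
    obs = _coerce_obs(obs)
    adata = ad.AnnData(
        X=counts,
        obs=obs,
        var=pd.DataFrame(index=pd.Index(np.asarray(gene_names, dtype=str), name="gene")),
    )
    adata.obsm["spatial"] = np.column_stack(
        [obs["x"].to_numpy(float), obs["y"].to_numpy(float)]
    )
    for name, mat in (layers or {}).items():
        adata.layers[name] = mat
    return adata


def _coerce_obs(obs: pd.DataFrame) -> pd.DataFrame:
    for col in NUMERIC_OBS:
        if col in obs.columns:
            try:
                obs[col] = pd.to_numeric(obs[col])
            except (ValueError, TypeError) as exc:
                raise SchemaError(f"column {col!r} is not numeric: {exc}") from exc
    for col in CATEGORICAL_OBS:
        if col in obs.columns and not isinstance(obs[col].dtype, pd.CategoricalDtype):
            obs[col] = pd.Categorical(obs[col].astype(str))
    return obs


def validate_dataset(adata: ad.AnnData) -> list[str]:
    """Check dataset invariants; return a report of violations (never raises).

    An empty list means the dataset is valid. Each entry names the
    offending cells/genes where applicable.
    """
    report: list[str] = []
    for col in REQUIRED_OBS:
        if col not in adata.obs.columns:
            report.append(f"missing required column: {col!r}")
    if adata.obs_names.has_duplicates:
        dups = adata.obs_names[adata.obs_names.duplicated()].unique().tolist()
        report.append(f"duplicate cell_id: {dups[:10]}")
    if adata.var_names.has_duplicates:
        dups = adata.var_names[adata.var_names.duplicated()].unique().tolist()
        report.append(f"duplicate gene names: {dups[:10]}")

    X = adata.X
    if X is not None:
        data = X.data if sp.issparse(X) else np.asarray(X)
        if data.size and np.nanmin(data) < 0:
            report.append("counts contain negative values")
        if data.size and not np.allclose(data, np.round(data)):
            report.append("counts are not integer-valued")
    for name, layer in adata.layers.items():
        if layer.shape != adata.shape:
            report.append(f"layer {name!r} shape {layer.shape} != {adata.shape}")

    for col in ("x", "y"):
        if col in adata.obs.columns:
            vals = pd.to_numeric(adata.obs[col], errors="coerce").to_numpy()
            bad = ~np.isfinite(vals)
            if bad.any():
                report.append(
                    f"non-finite {col} for cells: {adata.obs_names[bad].tolist()[:10]}"
                )
    if "volume" in adata.obs.columns:
        vol = adata.obs["volume"].to_numpy(float)
        bad = ~(vol > 0)
        if bad.any():
            report.append(
                f"non-positive volume for cells: {adata.obs_names[bad].tolist()[:10]}"
            )
    if "age_months" in adata.obs.columns:
        age = pd.to_numeric(adata.obs["age_months"], errors="coerce")
        if age.isna().any():
            report.append(
                "missing/non-numeric age_months for cells: "
                f"{adata.obs_names[age.isna()].tolist()[:10]}"
            )
        elif (age <= 0).any():
            report.append("age_months must be positive")
        if "animal_id" in adata.obs.columns:
            nuniq = adata.obs.groupby("animal_id", observed=True)["age_months"].nunique()
            bad_animals = nuniq[nuniq > 1].index.tolist()
            if bad_animals:
                report.append(f"age inconsistent within animal: {bad_animals}")
    return report


def _require_valid(adata: ad.AnnData) -> None:
    report = validate_dataset(adata)
    if report:
        raise SchemaError("; ".join(report))


# ---------------------------------------------------------------------------
# readers / writers


def _infer_fmt(path: Path) -> str:
    if path.suffix == ".h5ad":
        return "h5ad"
    if path.is_dir() or path.suffix == "":
        if (path / "matrix.mtx").exists():
            return "mtx"
        if (path / "matrix.csv").exists():
            return "csv"
    raise ValueError(f"cannot infer format of {path}; pass fmt explicitly")


def load_dataset(path: str | Path, fmt: str | None = None) -> ad.AnnData:
    """Load a dataset from ``h5ad``, ``mtx`` or ``csv`` storage and validate it."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or _infer_fmt(path)
    if fmt == "h5ad":
        adata = ad.read_h5ad(path)
        adata.obs = _coerce_obs(adata.obs)
    elif fmt == "mtx":
        adata = _load_tabular(path, "mtx")
    elif fmt == "csv":
        adata = _load_tabular(path, "csv")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    for col in REQUIRED_OBS:
        if col not in adata.obs.columns:
            raise SchemaError(f"missing required column: {col!r}")
    if "spatial" not in adata.obsm:
        adata.obsm["spatial"] = np.column_stack(
            [adata.obs["x"].to_numpy(float), adata.obs["y"].to_numpy(float)]
        )
    return adata


def save_dataset(adata: ad.AnnData, path: str | Path, fmt: str | None = None) -> Path:
    """Write a dataset so that :func:`load_dataset` reproduces it.

    Integer counts round-trip bit-for-bit in every format; float layers
    round-trip exactly in h5ad and to full double precision in mtx/csv.
    """
    path = Path(path)
    if fmt is None:
        fmt = "h5ad" if path.suffix == ".h5ad" else _infer_fmt_for_save(path)
    if fmt == "h5ad":
        path.parent.mkdir(parents=True, exist_ok=True)
        adata.write_h5ad(path)
        return path
    if fmt in ("mtx", "csv"):
        path.mkdir(parents=True, exist_ok=True)
        _save_tabular(adata, path, fmt)
        return path
    raise ValueError(f"unknown format {fmt!r}")


def _infer_fmt_for_save(path: Path) -> str:
    # directories default to mtx unless a csv matrix already lives there
    if path.suffix == ".h5ad":
        return "h5ad"
    if (path / "matrix.csv").exists():
        return "csv"
    return "mtx"


def _counts_matrix(adata: ad.AnnData) -> np.ndarray | sp.spmatrix:
    X = adata.X
    return X.tocoo() if sp.issparse(X) else np.asarray(X)


def _save_tabular(adata: ad.AnnData, outdir: Path, fmt: str) -> None:
    sep = "\t" if fmt == "mtx" else ","
    ext = "tsv" if fmt == "mtx" else "csv"
    obs = adata.obs.copy()
    obs.index.name = "cell_id"
    obs.to_csv(outdir / f"cells.{ext}", sep=sep)
    genes = pd.DataFrame(index=adata.var_names)
    genes.index.name = "gene"
    genes.to_csv(outdir / f"genes.{ext}", sep=sep)

    if fmt == "mtx":
        scipy.io.mmwrite(outdir / "matrix.mtx", sp.coo_matrix(_counts_matrix(adata)))
        for name, layer in adata.layers.items():
            dense = layer.toarray() if sp.issparse(layer) else np.asarray(layer)
            scipy.io.mmwrite(outdir / f"layer_{name}.mtx", sp.coo_matrix(dense), precision=17)
    else:
        dense = adata.X.toarray() if sp.issparse(adata.X) else np.asarray(adata.X)
        pd.DataFrame(dense, index=adata.obs_names, columns=adata.var_names).to_csv(
            outdir / "matrix.csv"
        )
        for name, layer in adata.layers.items():
            ldense = layer.toarray() if sp.issparse(layer) else np.asarray(layer)
            pd.DataFrame(ldense, index=adata.obs_names, columns=adata.var_names).to_csv(
                outdir / f"layer_{name}.csv", float_format="%.17g"
            )


def _load_tabular(indir: Path, fmt: str) -> ad.AnnData:
    sep = "\t" if fmt == "mtx" else ","
    ext = "tsv" if fmt == "mtx" else "csv"
    cells_path = indir / f"cells.{ext}"
    genes_path = indir / f"genes.{ext}"
    if not cells_path.exists() or not genes_path.exists():
        raise SchemaError(f"missing sidecar tables in {indir}")
    obs = pd.read_csv(cells_path, sep=sep, index_col=0)
    obs.index = obs.index.astype(str)
    obs.index.name = None
    genes = pd.read_csv(genes_path, sep=sep, index_col=0)
    gene_names = genes.index.astype(str)

    layers: dict[str, np.ndarray] = {}
    if fmt == "mtx":
        counts = sp.csr_matrix(scipy.io.mmread(indir / "matrix.mtx"))
        if np.allclose(counts.data, np.round(counts.data)):
            counts = counts.astype(np.int64)
        for f in sorted(indir.glob("layer_*.mtx")):
            m = scipy.io.mmread(f)
            layers[f.stem[len("layer_"):]] = (
                np.asarray(m.todense()) if sp.issparse(m) else np.asarray(m)
            )
    else:
        mat = pd.read_csv(indir / "matrix.csv", index_col=0)
        counts = mat.to_numpy()
        if np.allclose(counts, np.round(counts)):
            counts = counts.astype(np.int64)
        for f in sorted(indir.glob("layer_*.csv")):
            layers[f.stem[len("layer_"):]] = pd.read_csv(f, index_col=0).to_numpy(float)

    obs = _coerce_obs(obs)
    adata = ad.AnnData(X=counts, obs=obs, var=pd.DataFrame(index=gene_names))
    for name, mat in layers.items():
        adata.layers[name] = mat
    return adata


def to_dense(mat) -> np.ndarray:
    """Return a dense float64 ndarray view/copy of a matrix or sparse matrix."""
    if sp.issparse(mat):
        return np.asarray(mat.todense(), dtype=np.float64)
    return np.asarray(mat, dtype=np.float64)
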
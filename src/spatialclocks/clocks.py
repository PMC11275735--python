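"""Cell-type-specific lasso aging clocks.

A clock for one cell type is a pipeline: per-gene standardization of
graph-smoothed log-normalized expression, followed by a lasso linear model
predicting chronological age (months). The penalty is chosen by internal
cross-validation over a data-driven log-spaced path (LassoCV, 5 folds, 20
penalties, max_iter 10000), and the final model is refit on all training
cells.

Age acceleration of a cell is its predicted age minus the mean predicted
age over cells sharing its sample and cell type, so within every
(sample, cell type) group the accelerations average exactly zero.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, pearsonr
from sklearn.linear_model import LassoCV
from sklearn.model_selection import GroupKFold
from sklearn.preprocessing import StandardScaler

from .config import ClockConfig, SmoothingConfig
from .data_io import to_dense
from .smoothing import smooth_dataset


@dataclass
class ClockModel:
    """Fitted standardizer + lasso for one cell type.

    Prediction is affine in the standardized expression:
    ``age = ((x - mean) / scale) @ coef + intercept``.
    """

    cell_type: str
    genes: list[str]
    mean: np.ndarray
    scale: np.ndarray
    coef: np.ndarray
    intercept: float
    penalty: float
    config: ClockConfig = field(default_factory=ClockConfig)
    smoothing: SmoothingConfig | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        return ((X - self.mean) / self.scale) @ self.coef + self.intercept

    def to_dict(self) -> dict:
        d = {
            "cell_type": self.cell_type,
            "genes": list(self.genes),
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
            "coef": self.coef.tolist(),
            "intercept": float(self.intercept),
            "penalty": float(self.penalty),
            "config": vars(self.config).copy(),
        }
        if self.smoothing is not None:
            d["smoothing"] = vars(self.smoothing).copy()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ClockModel":
        return cls(
            cell_type=d["cell_type"],
            genes=list(d["genes"]),
            mean=np.asarray(d["mean"], float),
            scale=np.asarray(d["scale"], float),
            coef=np.asarray(d["coef"], float),
            intercept=float(d["intercept"]),
            penalty=float(d["penalty"]),
            config=ClockConfig(**d.get("config", {})),
            smoothing=SmoothingConfig(**d["smoothing"]) if "smoothing" in d else None,
        )


def save_clocks(models: dict[str, ClockModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({k: m.to_dict() for k, m in models.items()}, fh)


def load_clocks(path: str | Path) -> dict[str, ClockModel]:
    with open(path) as fh:
        return {k: ClockModel.from_dict(d) for k, d in json.load(fh).items()}


def _type_mask(adata: ad.AnnData, cell_type: str) -> np.ndarray:
    return (adata.obs["cell_type"].astype(str) == cell_type).to_numpy()


def train_clock(
    adata: ad.AnnData,
    cell_type: str,
    cfg: ClockConfig | None = None,
    layer: str = "smoothed",
    smoothing: SmoothingConfig | None = None,
) -> ClockModel:
    """Fit the aging clock for one cell type on the given layer."""
    cfg = cfg or ClockConfig()
    mask = _type_mask(adata, cell_type)
    if not mask.any():
        raise ValueError(f"no cells of type {cell_type!r}")
    X = to_dense(adata.layers[layer])[mask]
    y = adata.obs["age_months"].to_numpy(float)[mask]
    if np.unique(y).size < 2:
        raise ValueError("age has no variance among training cells")

    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    if cfg.group_folds_by_animal:
        groups = adata.obs["animal_id"].astype(str).to_numpy()[mask]
        cv = list(GroupKFold(n_splits=cfg.cv_folds).split(Xs, y, groups))
    else:
        cv = cfg.cv_folds
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings on noisy folds
        lasso = LassoCV(alphas=cfg.n_penalties, cv=cv, max_iter=cfg.max_iter).fit(Xs, y)
    return ClockModel(
        cell_type=cell_type,
        genes=adata.var_names.tolist(),
        mean=scaler.mean_.copy(),
        scale=scaler.scale_.copy(),
        coef=lasso.coef_.copy(),
        intercept=float(lasso.intercept_),
        penalty=float(lasso.alpha_),
        config=cfg,
        smoothing=smoothing,
    )


def predict_age(
    model: ClockModel, adata: ad.AnnData, layer: str = "smoothed"
) -> pd.DataFrame:
    """Predict age for every cell of the model's cell type.

    Requires the layer to cover all the model's genes (see
    :func:`apply_external` for partially overlapping panels). Predictions
    are not clipped to any age range.
    """
    missing = [g for g in model.genes if g not in adata.var_names]
    if missing:
        raise ValueError(f"dataset lacks clock genes: {missing[:10]} "
                         f"({len(missing)} total); use apply_external with an imputer")
    mask = _type_mask(adata, model.cell_type)
    sub = adata[mask]
    X = to_dense(sub.layers[layer])[:, [sub.var_names.get_loc(g) for g in model.genes]]
    out = pd.DataFrame(
        {
            "cell_id": sub.obs_names,
            "cell_type": model.cell_type,
            "sample_id": sub.obs["sample_id"].astype(str).to_numpy(),
            "animal_id": sub.obs["animal_id"].astype(str).to_numpy(),
            "age_months": sub.obs["age_months"].to_numpy(float),
            "predicted_age": model.predict(X),
        }
    ).set_index("cell_id")
    return out


def age_acceleration(
    predictions: pd.DataFrame, grouping: tuple[str, str] = ("sample_id", "cell_type")
) -> pd.DataFrame:
    """Add ``age_acceleration``: predicted age minus the mean predicted age
    of the cell's (sample, cell type) group. Group means of the result are
    zero by construction."""
    out = predictions.copy()
    group_mean = out.groupby(list(grouping), observed=True)["predicted_age"].transform("mean")
    out["age_acceleration"] = out["predicted_age"] - group_mean
    return out


@dataclass
class ClockMetrics:
    cell_type: str
    cell_r: float       # Pearson R, per-cell predicted vs chronological age
    cell_mae: float     # months
    animal_r: float     # Pearson r of per-animal median predicted age vs age
    n_cells: int
    n_animals: int


def compute_metrics(predictions: pd.DataFrame, cell_type: str) -> ClockMetrics:
    y = predictions["age_months"].to_numpy(float)
    p = predictions["predicted_age"].to_numpy(float)
    cell_r = float(pearsonr(y, p)[0]) if len(y) > 1 and np.std(y) > 0 else np.nan
    med = predictions.groupby("animal_id", observed=True).agg(
        age=("age_months", "first"), pred=("predicted_age", "median")
    )
    animal_r = (
        float(pearsonr(med["age"], med["pred"])[0])
        if len(med) > 1 and med["age"].std() > 0
        else np.nan
    )
    return ClockMetrics(
        cell_type=cell_type,
        cell_r=cell_r,
        cell_mae=float(np.mean(np.abs(p - y))),
        animal_r=animal_r,
        n_cells=len(y),
        n_animals=med.shape[0],
    )


def evaluate_leave_one_animal_out(
    adata: ad.AnnData,
    cell_type: str,
    cfg: ClockConfig | None = None,
    smoothing: SmoothingConfig | None = None,
    source: str = "lognorm",
) -> tuple[pd.DataFrame, ClockMetrics]:
    """Cross-validated evaluation: hold out one animal at a time.

    Graph smoothing is confined to single sections, and train/test
    partitions are whole animals, so smoothing each partition separately is
    identical to smoothing each section once; standardization and the lasso
    are refit per fold on the training partition only.
    """
    cfg = cfg or ClockConfig()
    smoothing = smoothing or SmoothingConfig()
    animals = adata.obs["animal_id"].astype(str)
    uniq = animals.unique().tolist()
    if len(uniq) < 3:
        raise ValueError("leave-one-animal-out needs >= 3 animals")
    if "smoothed" not in adata.layers:
        smooth_dataset(adata, smoothing, source=source)
    mask_type = _type_mask(adata, cell_type)
    preds = []
    for held in uniq:
        test_mask = (animals == held).to_numpy()
        if not (mask_type & test_mask).any():
            continue  # no test cells of this type in the fold
        train = adata[~test_mask]
        if np.unique(train.obs["age_months"][_type_mask(train, cell_type)]).size < 2:
            continue
        model = train_clock(train, cell_type, cfg, layer="smoothed", smoothing=smoothing)
        preds.append(predict_age(model, adata[test_mask], layer="smoothed"))
    if not preds:
        raise ValueError("no usable folds")
    table = pd.concat(preds)
    return table, compute_metrics(table, cell_type)


def cross_validated_predictions(
    adata: ad.AnnData,
    cell_types: list[str],
    n_folds: int | None = None,
    cfg: ClockConfig | None = None,
    smoothing: SmoothingConfig | None = None,
    source: str = "lognorm",
    layer_predict: str = "smoothed",
) -> pd.DataFrame:
    """Out-of-fold predicted ages for the listed cell types.

    ``n_folds=None`` gives leave-one-animal-out; otherwise animals are
    partitioned into ``n_folds`` groups (round-robin in sorted order). Set
    ``layer_predict="lognorm"`` to predict without the smoothing step (the
    non-spatial "SS" clock variant).
    """
    cfg = cfg or ClockConfig()
    smoothing = smoothing or SmoothingConfig()
    if "smoothed" not in adata.layers:
        smooth_dataset(adata, smoothing, source=source)
    animals = adata.obs["animal_id"].astype(str)
    uniq = sorted(animals.unique().tolist())
    k = len(uniq) if n_folds is None else min(n_folds, len(uniq))
    fold_of = {a: i % k for i, a in enumerate(uniq)}
    folds = animals.map(fold_of).to_numpy()
    preds = []
    for f in range(k):
        test_mask = folds == f
        train = adata[~test_mask]
        test = adata[test_mask]
        for ctype in cell_types:
            if not _type_mask(test, ctype).any():
                continue
            model = train_clock(train, ctype, cfg, layer="smoothed", smoothing=smoothing)
            preds.append(predict_age(model, test, layer=layer_predict))
    return pd.concat(preds)


def apply_external(
    model: ClockModel,
    adata: ad.AnnData,
    gene_map: dict[str, str] | None = None,
    imputer=None,
    smoothing: SmoothingConfig | None = None,
    spatial: bool = True,
    pseudocell_size: int = 20,
    seed: int = 0,
    min_coverage: float = 0.2,
    strict: bool = False,
) -> tuple[pd.DataFrame, float]:
    """Apply a clock to an external dataset with a partially matching panel.

    The dataset is subset to the clock's genes (after renaming via
    ``gene_map``), smoothed per cell type (or, for non-spatial data,
    replaced by pseudocell averages of ``pseudocell_size`` same-type cells),
    and missing clock genes are filled by ``imputer(genes, adata) ->
    (n_cells, n_missing)`` — per-gene training-mean fill by default.
    Negative imputed values are clipped to zero. Returns the predictions and
    the clock-gene coverage fraction.
    """
    smoothing = smoothing or SmoothingConfig()
    work = adata.copy()
    if gene_map:
        work.var_names = [gene_map.get(g, g) for g in work.var_names]
    present = [g for g in model.genes if g in work.var_names]
    coverage = len(present) / len(model.genes)
    if coverage < min_coverage:
        msg = (f"only {coverage:.0%} of clock genes observed "
               f"({len(present)}/{len(model.genes)})")
        if strict:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)

    work = work[:, [work.var_names.get_loc(g) for g in present]].copy()
    if "lognorm" not in work.layers:
        from .preprocess import log_normalize

        log_normalize(work)
    if spatial:
        smooth_dataset(work, smoothing, source="lognorm", cell_types=[model.cell_type])
        vals = to_dense(work.layers["smoothed"])
    else:
        vals = _pseudocell_average(work, pseudocell_size, seed)
    mask = _type_mask(work, model.cell_type)
    sub_vals = vals[mask]

    gene_pos = {g: i for i, g in enumerate(present)}
    X = np.empty((mask.sum(), len(model.genes)))
    missing = [g for g in model.genes if g not in gene_pos]
    if missing:
        if imputer is None:
            tm = {g: m for g, m in zip(model.genes, model.mean)}
            imputed = np.tile([tm[g] for g in missing], (int(mask.sum()), 1))
        else:
            imputed = np.asarray(imputer(missing, work))[mask]
        imputed = np.clip(imputed, 0.0, None)  # negative imputed values -> 0
    for j, g in enumerate(model.genes):
        if g in gene_pos:
            X[:, j] = sub_vals[:, gene_pos[g]]
        else:
            X[:, j] = imputed[:, missing.index(g)]

    sub = work[mask]
    out = pd.DataFrame(
        {
            "cell_id": sub.obs_names,
            "cell_type": model.cell_type,
            "sample_id": sub.obs["sample_id"].astype(str).to_numpy()
            if "sample_id" in sub.obs
            else "sample0",
            "animal_id": sub.obs["animal_id"].astype(str).to_numpy(),
            "age_months": sub.obs["age_months"].to_numpy(float)
            if "age_months" in sub.obs
            else np.nan,
            "predicted_age": model.predict(X),
        }
    ).set_index("cell_id")
    return out, coverage


def _pseudocell_average(adata: ad.AnnData, size: int, seed: int) -> np.ndarray:
    """Non-spatial fallback: each cell's profile becomes the mean of ``size``
    randomly drawn same-type same-animal cells (always including itself)."""
    rng = np.random.default_rng(seed)
    X = to_dense(adata.layers["lognorm"])
    out = np.empty_like(X)
    ctype = adata.obs["cell_type"].astype(str).to_numpy()
    animal = adata.obs["animal_id"].astype(str).to_numpy()
    keys = pd.Series(list(zip(ctype, animal)))
    for _, idx in keys.groupby(keys).groups.items():
        idx = np.asarray(idx)
        for i in idx:
            draw = rng.choice(idx, size=min(size - 1, len(idx)), replace=True)
            out[i] = X[np.concatenate([[i], draw])].mean(axis=0)
    return out


def train_pseudobulk_clock(
    adata: ad.AnnData,
    cell_type: str,
    n_boot: int = 1000,
    cells_per_boot: int = 30,
    seed: int = 0,
    cfg: ClockConfig | None = None,
) -> ClockModel:
    """Non-spatial "SingleCell (PB)" clock variant: per animal, training rows
    are bootstrap means of ``cells_per_boot`` cells' log-normalized
    expression; the lasso pipeline is unchanged. With ``n_boot=1`` and
    ``cells_per_boot=None`` this reduces to the plain animal-mean pseudobulk
    fit."""
    cfg = cfg or ClockConfig()
    rng = np.random.default_rng(seed)
    mask = _type_mask(adata, cell_type)
    X = to_dense(adata.layers["lognorm"])[mask]
    y = adata.obs["age_months"].to_numpy(float)[mask]
    animal = adata.obs["animal_id"].astype(str).to_numpy()[mask]
    rows, ages = [], []
    for a in pd.unique(animal):
        idx = np.flatnonzero(animal == a)
        if cells_per_boot is None:
            rows.append(X[idx].mean(axis=0))
            ages.append(y[idx[0]])
            continue
        if len(idx) < cells_per_boot:
            raise ValueError(
                f"animal {a!r} has {len(idx)} cells of {cell_type!r}; "
                f"needs >= {cells_per_boot}"
            )
        for _ in range(n_boot):
            draw = rng.choice(idx, size=cells_per_boot, replace=True)
            rows.append(X[draw].mean(axis=0))
            ages.append(y[idx[0]])
    Xp = np.vstack(rows)
    yp = np.asarray(ages)
    if np.unique(yp).size < 2:
        raise ValueError("age has no variance among training animals")
    scaler = StandardScaler().fit(Xp)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lasso = LassoCV(alphas=cfg.n_penalties, cv=cfg.cv_folds, max_iter=cfg.max_iter).fit(
            scaler.transform(Xp), yp
        )
    return ClockModel(
        cell_type=cell_type,
        genes=adata.var_names.tolist(),
        mean=scaler.mean_.copy(),
        scale=scaler.scale_.copy(),
        coef=lasso.coef_.copy(),
        intercept=float(lasso.intercept_),
        penalty=float(lasso.alpha_),
        config=cfg,
        smoothing=None,
    )


def intervention_effect(
    pred_control: pd.DataFrame,
    pred_intervention: pd.DataFrame,
    cell_type: str | None = None,
    region: str | None = None,
    region_col: str = "region",
    age_correction: float = 0.0,
    min_cells: int = 50,
) -> dict:
    """Difference in median predicted age, intervention minus control.

    ``age_correction`` (months) is added to the intervention predictions
    before the medians are compared, correcting for a mean-age mismatch
    between arms. Two-sided Mann-Whitney tests are reported at the cell
    level and on per-animal medians. In regional mode (``region`` given), a
    group with fewer than ``min_cells`` cells marks the record insufficient.
    """
    def _subset(df: pd.DataFrame) -> pd.DataFrame:
        if cell_type is not None:
            df = df[df["cell_type"] == cell_type]
        if region is not None:
            df = df[df[region_col] == region]
        return df

    ctrl = _subset(pred_control)
    intv = _subset(pred_intervention)
    iv = intv["predicted_age"].to_numpy(float) + age_correction
    cv = ctrl["predicted_age"].to_numpy(float)
    record = {
        "cell_type": cell_type,
        "region": region,
        "n_control": len(cv),
        "n_intervention": len(iv),
        "effect_months": float(np.median(iv) - np.median(cv))
        if len(iv) and len(cv)
        else np.nan,
        "insufficient": region is not None
        and (len(cv) < min_cells or len(iv) < min_cells),
    }
    if len(iv) and len(cv):
        record["p_cell"] = float(mannwhitneyu(iv, cv, alternative="two-sided").pvalue)
        med_i = intv.groupby("animal_id", observed=True)["predicted_age"].median() + age_correction
        med_c = ctrl.groupby("animal_id", observed=True)["predicted_age"].median()
        if len(med_i) > 1 and len(med_c) > 1:
            record["p_animal"] = float(
                mannwhitneyu(med_i, med_c, alternative="two-sided").pvalue
            )
        else:
            record["p_animal"] = np.nan
    else:
        record["p_cell"] = np.nan
        record["p_animal"] = np.nan
    return record
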
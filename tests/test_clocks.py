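"""Lasso aging clocks: training, prediction, acceleration, variants."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import Lasso
from sklearn.preprocessing import StandardScaler

import spatialclocks as spc
from spatialclocks.config import ClockConfig
from spatialclocks.data_io import to_dense

from conftest import tiny_dataset


def _clock_fixture(n_cells=300, seed=0, signal_gene=0):
    """Cells whose smoothed gene 0 is exactly 0.1 x age; rest noise."""
    rng = np.random.default_rng(seed)
    ds = tiny_dataset(n_cells=n_cells, n_genes=10, seed=seed)
    ages = rng.choice(np.linspace(3, 30, 10), size=n_cells)
    ds.obs["age_months"] = ages
    ds.obs["animal_id"] = [f"m{a:.0f}" for a in ages]
    ds.obs["sample_id"] = ds.obs["animal_id"]
    ds.obs["cell_type"] = "A"
    X = rng.normal(size=(n_cells, 10))
    X[:, signal_gene] = 0.1 * ages
    ds.layers["smoothed"] = X
    return ds


def test_exact_linear_gene_is_recovered():
    ds = _clock_fixture()
    model = spc.train_clock(ds, "A")
    preds = model.predict(to_dense(ds.layers["smoothed"]))
    mae = np.abs(preds - ds.obs["age_months"].to_numpy()).mean()
    assert mae < 0.5


def test_pure_noise_gives_heavy_penalty_and_mean_prediction():
    rng = np.random.default_rng(1)
    ds = _clock_fixture(seed=1)
    ds.layers["smoothed"] = rng.normal(size=ds.shape)  # destroy the signal
    model = spc.train_clock(ds, "A")
    preds = model.predict(to_dense(ds.layers["smoothed"]))
    mean_age = ds.obs["age_months"].mean()
    assert np.abs(preds - mean_age).max() < 3.0
    r = np.corrcoef(preds, ds.obs["age_months"])[0, 1] if preds.std() > 0 else 0.0
    assert abs(r) < 0.35


def test_duplicating_cells_reproduces_coefficients_at_same_penalty():
    ds = _clock_fixture(seed=2)
    model = spc.train_clock(ds, "A")
    X = to_dense(ds.layers["smoothed"])
    Xd = np.vstack([X, X])
    yd = np.concatenate([ds.obs["age_months"]] * 2)
    scaler = StandardScaler().fit(Xd)
    refit = Lasso(alpha=model.penalty, max_iter=10000).fit(scaler.transform(Xd), yd)
    np.testing.assert_allclose(refit.coef_, model.coef, atol=1e-6)


def test_single_age_raises():
    ds = _clock_fixture()
    ds.obs["age_months"] = 12.0
    with pytest.raises(ValueError, match="no variance"):
        spc.train_clock(ds, "A")


def test_predict_zero_coefficients_gives_intercept():
    ds = _clock_fixture(seed=3)
    model = spc.train_clock(ds, "A")
    model.coef = np.zeros_like(model.coef)
    model.intercept = 12.0
    out = spc.predict_age(model, ds)
    np.testing.assert_allclose(out["predicted_age"], 12.0)


def test_hand_built_two_gene_model_matches_dot_product():
    ds = tiny_dataset(n_cells=3, n_genes=2)
    ds.obs["cell_type"] = "A"
    ds.obs["sample_id"] = "s0"
    X = np.array([[1.0, 2.0], [0.0, 1.0], [2.0, 0.0]])
    ds.layers["smoothed"] = X
    model = spc.ClockModel(
        cell_type="A", genes=["g0", "g1"],
        mean=np.array([1.0, 1.0]), scale=np.array([2.0, 0.5]),
        coef=np.array([3.0, -1.0]), intercept=10.0, penalty=0.1,
    )
    expected = ((X - [1, 1]) / [2, 0.5]) @ [3, -1] + 10
    out = spc.predict_age(model, ds)
    np.testing.assert_allclose(out["predicted_age"], expected)


def test_training_data_through_model_equals_fit_time_predictions():
    ds = _clock_fixture(seed=4)
    model = spc.train_clock(ds, "A")
    direct = model.predict(to_dense(ds.layers["smoothed"]))
    via_api = spc.predict_age(model, ds)["predicted_age"].to_numpy()
    np.testing.assert_allclose(direct, via_api)


def test_age_shift_equivariance():
    ds = _clock_fixture(seed=5)
    m1 = spc.train_clock(ds, "A")
    shifted = ds.copy()
    shifted.obs["age_months"] = shifted.obs["age_months"] + 7.0
    m2 = spc.train_clock(shifted, "A")
    np.testing.assert_allclose(m2.coef, m1.coef, atol=1e-10)
    assert m2.intercept - m1.intercept == pytest.approx(7.0, abs=1e-8)


def test_model_json_roundtrip(tmp_path):
    ds = _clock_fixture(seed=6)
    model = spc.train_clock(ds, "A")
    spc.save_clocks({"A": model}, tmp_path / "clocks.json")
    back = spc.load_clocks(tmp_path / "clocks.json")["A"]
    X = to_dense(ds.layers["smoothed"])
    np.testing.assert_allclose(back.predict(X), model.predict(X))


# --- age acceleration ------------------------------------------------------


def _pred_frame(pred, sample, ctype="A"):
    return pd.DataFrame(
        {
            "cell_type": ctype,
            "sample_id": sample,
            "animal_id": sample,
            "age_months": 10.0,
            "predicted_age": pred,
        },
        index=[f"c{i}" for i in range(len(pred))],
    )


def test_acceleration_examples():
    single = spc.age_acceleration(_pred_frame([17.0], ["s0"]))
    assert single["age_acceleration"].iloc[0] == 0.0
    pair = spc.age_acceleration(_pred_frame([10.0, 14.0], ["s0", "s0"]))
    np.testing.assert_allclose(pair["age_acceleration"], [-2.0, 2.0])


def test_acceleration_group_means_are_zero(ds8):
    rng = np.random.default_rng(7)
    obs = ds8.obs
    preds = pd.DataFrame(
        {
            "cell_type": obs["cell_type"].astype(str).to_numpy(),
            "sample_id": obs["sample_id"].astype(str).to_numpy(),
            "animal_id": obs["animal_id"].astype(str).to_numpy(),
            "age_months": obs["age_months"].to_numpy(float),
            "predicted_age": rng.normal(15, 5, ds8.n_obs),
        },
        index=obs.index,
    )
    acc = spc.age_acceleration(preds)
    means = acc.groupby(["sample_id", "cell_type"], observed=True)["age_acceleration"].mean()
    np.testing.assert_allclose(means.to_numpy(), 0.0, atol=1e-9)


# --- leave-one-animal-out --------------------------------------------------


def test_loo_metrics_consistent_with_returned_table(ds8):
    ds = ds8.copy()
    table, metrics = spc.evaluate_leave_one_animal_out(ds, "Oligodendrocyte")
    recomputed = spc.compute_metrics(table, "Oligodendrocyte")
    assert recomputed.cell_r == pytest.approx(metrics.cell_r)
    assert recomputed.cell_mae == pytest.approx(metrics.cell_mae)
    assert metrics.cell_r > 0.8  # well-specified small fixture


def test_loo_requires_three_animals():
    ds = _clock_fixture()
    ds.obs["animal_id"] = np.where(np.arange(ds.n_obs) % 2 == 0, "m0", "m1")
    ds.obs["age_months"] = np.where(np.arange(ds.n_obs) % 2 == 0, 5.0, 20.0)
    with pytest.raises(ValueError, match=">= 3 animals"):
        spc.evaluate_leave_one_animal_out(ds, "A")


def test_no_leakage_mutating_test_cells_leaves_train_smoothing_unchanged(ds8):
    held = ds8.obs["animal_id"].astype(str).unique()[0]
    test_mask = (ds8.obs["animal_id"].astype(str) == held).to_numpy()
    mutated = ds8.copy()
    lognorm = to_dense(mutated.layers["lognorm"])
    lognorm[test_mask] += 100.0
    mutated.layers["lognorm"] = lognorm
    del mutated.layers["smoothed"]
    spc.smooth_dataset(mutated)
    orig = to_dense(ds8.layers["smoothed"])
    new = to_dense(mutated.layers["smoothed"])
    np.testing.assert_allclose(new[~test_mask], orig[~test_mask])
    assert np.abs(new[test_mask] - orig[test_mask]).max() > 1.0


# --- external application and variants -------------------------------------


def test_apply_external_full_panel_matches_predict(ds8):
    model = spc.train_clock(ds8, "Astrocyte")
    direct = spc.predict_age(model, ds8)
    ext = ds8.copy()
    preds, coverage = spc.apply_external(model, ext)
    assert coverage == 1.0
    merged = direct.join(preds, rsuffix="_ext")
    np.testing.assert_allclose(
        merged["predicted_age"], merged["predicted_age_ext"], atol=1e-9
    )


def test_apply_external_all_missing_gives_intercept(ds8):
    model = spc.train_clock(ds8, "Astrocyte")
    ext = ds8.copy()
    ext.var_names = ["zz" + g for g in ext.var_names]
    with pytest.warns(UserWarning, match="clock genes"):
        preds, coverage = spc.apply_external(model, ext)
    assert coverage == 0.0
    np.testing.assert_allclose(preds["predicted_age"], model.intercept, atol=1e-9)


def test_pseudobulk_limiting_case_equals_animal_mean_fit(ds8):
    m1 = spc.train_pseudobulk_clock(ds8, "Astrocyte", n_boot=1, cells_per_boot=None, seed=0)
    m2 = spc.train_pseudobulk_clock(ds8, "Astrocyte", n_boot=5, cells_per_boot=None, seed=9)
    np.testing.assert_allclose(m1.coef, m2.coef)  # no resampling -> seed irrelevant


def test_pseudobulk_fixed_seed_is_deterministic(ds8):
    kw = dict(n_boot=20, cells_per_boot=10, seed=3)
    m1 = spc.train_pseudobulk_clock(ds8, "Oligodendrocyte", **kw)
    m2 = spc.train_pseudobulk_clock(ds8, "Oligodendrocyte", **kw)
    np.testing.assert_array_equal(m1.coef, m2.coef)


# --- intervention effects ---------------------------------------------------


def test_intervention_identical_groups():
    preds = _pred_frame(np.linspace(10, 20, 80), ["s%d" % (i % 4) for i in range(80)])
    rec = spc.intervention_effect(preds, preds.copy())
    assert rec["effect_months"] == 0.0
    assert rec["p_cell"] > 0.9


def test_intervention_age_correction_is_affine():
    preds = _pred_frame(np.linspace(10, 20, 60), ["s0"] * 60)
    rec = spc.intervention_effect(preds, preds.copy(), age_correction=0.3)
    assert rec["effect_months"] == pytest.approx(0.3)


def test_intervention_regional_insufficient_flag():
    preds = _pred_frame(np.arange(10.0), ["s0"] * 10)
    preds["region"] = "CTX"
    rec = spc.intervention_effect(preds, preds.copy(), region="CTX", min_cells=50)
    assert rec["insufficient"]
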
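"""Trajectory construction, archetype clustering, aging-gene screens."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import spatialclocks as spc
from spatialclocks.trajectories import (
    _locf,
    aging_gene_screen,
    build_trajectories,
    cluster_trajectories,
    regional_change_magnitude,
    smooth_trajectory,
)

from conftest import tiny_dataset


def _age_series_dataset(present_ages, all_ages, n_genes=4, seed=0):
    """One cell type / subregion observed only at ``present_ages``."""
    rng = np.random.default_rng(seed)
    rows = []  # (age, animal, xy, cell_type, subregion)
    for a in all_ages:
        n = 20 if a in present_ages else 0
        for i in range(n):
            rows.append((a, f"m{a:.0f}", rng.uniform(0, 100, 2), "A", "S"))
        for i in range(5):  # filler type so every age is profiled in the study
            rows.append((a, f"m{a:.0f}", rng.uniform(0, 100, 2), "F", "S"))
    obs = pd.DataFrame(
        {
            "x": [r[2][0] for r in rows],
            "y": [r[2][1] for r in rows],
            "volume": 500.0,
            "cell_type": [r[3] for r in rows],
            "animal_id": [r[1] for r in rows],
            "age_months": [r[0] for r in rows],
            "subregion": [r[4] for r in rows],
        },
        index=[f"c{i}" for i in range(len(rows))],
    )
    counts = rng.poisson(8.0, size=(len(rows), n_genes))
    ds = spc.make_dataset(counts, [f"g{j}" for j in range(n_genes)], obs)
    spc.volume_normalize(ds)
    return ds


def test_fully_observed_trajectory_has_no_imputation():
    ages = list(np.linspace(3, 30, 10))
    ds = _age_series_dataset(ages, ages)
    tm = build_trajectories(ds)
    assert not tm.missing_mask.to_numpy().any()
    np.testing.assert_allclose(tm.values.mean(axis=1), 0.0, atol=1e-9)
    np.testing.assert_allclose(tm.values.std(axis=1, ddof=0), 1.0, atol=1e-9)


def test_locf_hand_example():
    mat = np.array([[1.0, np.nan, np.nan, 4.0, np.nan]])
    out = _locf(mat)
    np.testing.assert_allclose(out, [[1.0, 1.0, 1.0, 4.0, 4.0]])
    lead = _locf(np.array([[np.nan, np.nan, 2.0, 3.0]]))
    np.testing.assert_allclose(lead, [[2.0, 2.0, 2.0, 3.0]])


def test_locf_applied_at_internal_gap_via_build():
    all_ages = list(np.linspace(3, 30, 10))
    present = [a for i, a in enumerate(all_ages) if i not in (6, 7)]  # 8/10 = 80%
    ds = _age_series_dataset(present, all_ages, seed=1)
    tm = build_trajectories(ds)
    a_rows = tm.values.xs("A", level="cell_type")
    a_mask = tm.missing_mask.xs("A", level="cell_type")
    mask = a_mask.iloc[0].to_numpy()
    np.testing.assert_array_equal(np.flatnonzero(mask), [6, 7])
    vals = a_rows.iloc[0].to_numpy()
    assert vals[6] == vals[5] and vals[7] == vals[5]  # carried forward


def test_low_coverage_combination_dropped():
    all_ages = list(np.linspace(3, 30, 20))
    present = all_ages[:13]  # 65% < 70%
    ds = _age_series_dataset(present, all_ages, seed=2)
    tm = build_trajectories(ds)
    assert "A" not in tm.values.index.get_level_values("cell_type")
    assert tm.dropped_low_coverage > 0
    assert "F" in tm.values.index.get_level_values("cell_type")


def test_cluster_k1_centroid_is_column_mean():
    rng = np.random.default_rng(3)
    values = pd.DataFrame(rng.normal(size=(30, 10)))
    ids, centroids = cluster_trajectories(values, k=1, seed=444)
    assert (ids == 0).all()
    np.testing.assert_allclose(centroids.iloc[0], values.mean(axis=0), atol=1e-9)


def test_cluster_seeded_and_row_order_invariant():
    rng = np.random.default_rng(4)
    arche = rng.normal(size=(4, 12))
    rows = np.repeat(arche, 25, axis=0) + rng.normal(0, 0.1, (100, 12))
    values = pd.DataFrame(rows)
    ids1, _ = cluster_trajectories(values, k=4, seed=444)
    ids2, _ = cluster_trajectories(values, k=4, seed=444)
    np.testing.assert_array_equal(ids1.to_numpy(), ids2.to_numpy())
    perm = rng.permutation(100)
    ids3, _ = cluster_trajectories(values.iloc[perm], k=4, seed=444)
    assert adjusted_rand_score(ids1.to_numpy()[perm], ids3.to_numpy()) == 1.0


def test_cluster_k_exceeding_rows_raises():
    with pytest.raises(ValueError, match="exceeds"):
        cluster_trajectories(pd.DataFrame(np.zeros((3, 5))), k=9)


def test_spline_reproduces_line_and_interpolates_at_zero_smoothing():
    ages = np.linspace(3, 30, 12)
    line = 2.0 * ages - 5.0
    grid, sm = smooth_trajectory(ages, line, smoothing=20.0)
    np.testing.assert_allclose(sm, 2.0 * grid - 5.0, atol=1e-6)
    _, exact = smooth_trajectory(ages, line, smoothing=0.0, n_dense=12)
    np.testing.assert_allclose(
        smooth_trajectory(ages, line, smoothing=0.0)[1][0], line[0], atol=1e-8
    )


def test_spline_residual_decreases_with_smoothing():
    rng = np.random.default_rng(5)
    ages = np.linspace(0, 30, 20)
    noisy = np.sin(ages / 4) + rng.normal(0, 0.3, 20)
    sds = []
    for s in (0.0, 20.0, 200.0):
        grid, sm = smooth_trajectory(ages, noisy, smoothing=s, n_dense=20)
        at_knots = np.interp(ages, grid, sm)
        sds.append(np.std(noisy - at_knots))
    assert sds[0] <= sds[1] <= sds[2]
    assert sds[0] < 1e-8  # s=0 interpolates


def _screen_dataset(seed=0, n_samples=20, monotone_gene=0, constant_gene=1):
    rng = np.random.default_rng(seed)
    n_genes = 5
    rows, obs_rows = [], []
    for s in range(n_samples):
        age = 3.0 + 1.5 * s
        for i in range(10):
            obs_rows.append((f"s{s:02d}", f"s{s:02d}", age, rng.uniform(0, 50, 2)))
            base = rng.poisson(5.0, n_genes).astype(float)
            rows.append(base)
    X = np.asarray(rows)
    ages = np.array([r[2] for r in obs_rows])
    X[:, monotone_gene] = ages + rng.normal(0, 1e-6, len(ages))
    X[:, constant_gene] = 7.0
    obs = pd.DataFrame(
        {
            "x": [r[3][0] for r in obs_rows],
            "y": [r[3][1] for r in obs_rows],
            "volume": 500.0,
            "cell_type": "A",
            "animal_id": [r[0] for r in obs_rows],
            "sample_id": [r[1] for r in obs_rows],
            "age_months": ages,
        },
        index=[f"c{i}" for i in range(len(obs_rows))],
    )
    ds = spc.make_dataset(np.round(X).astype(int), [f"g{j}" for j in range(n_genes)], obs)
    ds.layers["lognorm"] = X
    return ds


def test_screen_monotone_and_constant_genes():
    ds = _screen_dataset()
    out = aging_gene_screen(ds, "A").set_index("gene")
    assert out.loc["g0", "rho"] == pytest.approx(1.0)
    assert out.loc["g0", "category"] == "Increasing"
    assert out.loc["g1", "category"] == "none"


def test_screen_antisymmetric_under_negation():
    ds = _screen_dataset(seed=1)
    out1 = aging_gene_screen(ds, "A").set_index("gene")
    ds.layers["lognorm"] = -np.asarray(ds.layers["lognorm"])
    out2 = aging_gene_screen(ds, "A").set_index("gene")
    swap = {"Increasing": "Decreasing", "Decreasing": "Increasing", "none": "none"}
    for g in out1.index:
        assert out2.loc[g, "category"] == swap[out1.loc[g, "category"]]


def test_screen_requires_four_samples():
    ds = _screen_dataset(n_samples=3)
    with pytest.raises(ValueError, match="4 samples"):
        aging_gene_screen(ds, "A")


def _regional_dataset(fold_genes, fold=2.0, n_genes=20, seed=0):
    """5 young + 5 old animals, one region; old counts scaled on fold_genes."""
    rng = np.random.default_rng(seed)
    rows, obs_rows = [], []
    for a in range(10):
        old = a >= 5
        age = 25.0 if old else 5.0
        for i in range(60):
            mu = np.full(n_genes, 20.0)
            if old:
                mu[fold_genes] *= fold
            rows.append(rng.poisson(mu * 40) / 40.0)  # low-noise profile
            obs_rows.append((f"m{a}", age, rng.uniform(0, 100, 2)))
    obs = pd.DataFrame(
        {
            "x": [r[2][0] for r in obs_rows],
            "y": [r[2][1] for r in obs_rows],
            "volume": 1.0,
            "cell_type": "A",
            "animal_id": [r[0] for r in obs_rows],
            "age_months": [r[1] for r in obs_rows],
            "region": "CTX",
        },
        index=[f"c{i}" for i in range(len(obs_rows))],
    )
    ds = spc.make_dataset(
        np.zeros((len(rows), n_genes), dtype=int), [f"g{j}" for j in range(n_genes)], obs
    )
    ds.layers["volnorm"] = np.asarray(rows)
    return ds


def test_regional_change_matches_analytic_expectation():
    n_genes = 20
    fold_genes = np.arange(n_genes // 2)
    ds = _regional_dataset(fold_genes, fold=2.0, n_genes=n_genes)
    out = regional_change_magnitude(ds, n_repeats=5, seed=0)
    assert len(out) == 1
    # doubling half the genes then renormalizing to a fixed total gives
    # |log(4/3)| on doubled genes and |log(2/3)| on the rest: mean ~ ln2 / 2
    expected = 0.5 * (np.log(4 / 3) + np.log(3 / 2))
    assert out["mean_abs_dlog"].iloc[0] == pytest.approx(expected, rel=0.2)


def test_regional_change_null_is_small_and_seeded():
    ds = _regional_dataset(np.array([], dtype=int), n_genes=20, seed=1)
    out1 = regional_change_magnitude(ds, n_repeats=5, seed=7)
    out2 = regional_change_magnitude(ds, n_repeats=5, seed=7)
    pd.testing.assert_frame_equal(out1, out2)
    planted = _regional_dataset(np.arange(10), n_genes=20, seed=1)
    planted_out = regional_change_magnitude(planted, n_repeats=5, seed=7)
    assert out1["mean_abs_dlog"].iloc[0] < 0.3 * planted_out["mean_abs_dlog"].iloc[0]
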
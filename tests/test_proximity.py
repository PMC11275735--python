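"""Near/Far matching, Cohen's d, permutation nulls, signatures."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import spatialclocks as spc
from spatialclocks.proximity import (
    cohens_d,
    label_near_far,
    levene_equal_variance,
    nearest_effector_distance,
    proximity_effect,
    signature_score,
    spatial_permutation_null,
    subtype_split,
)

from conftest import tiny_dataset


def _geo(xy, types, subregions=None, sample=None):
    ds = tiny_dataset(n_cells=len(xy), n_genes=4, seed=0)
    ds.obs["x"] = np.asarray(xy, float)[:, 0]
    ds.obs["y"] = np.asarray(xy, float)[:, 1]
    ds.obs["cell_type"] = list(types)
    ds.obs["sample_id"] = sample if sample is not None else "s0"
    ds.obs["subregion"] = list(subregions) if subregions is not None else "all"
    return ds


def test_nearest_effector_hand_example():
    ds = _geo([[0, 0], [3, 4]], ["E", "T"])
    d = nearest_effector_distance(ds, "E")
    assert d[1] == pytest.approx(5.0)


def test_nearest_effector_excludes_self():
    ds = _geo([[0, 0], [7, 0]], ["E", "E"])
    d = nearest_effector_distance(ds, "E")
    np.testing.assert_allclose(d, [7.0, 7.0])
    solo = _geo([[0, 0]], ["E"])
    assert np.isinf(nearest_effector_distance(solo, "E")[0])


def test_nearest_effector_matches_bruteforce():
    rng = np.random.default_rng(1)
    xy = rng.uniform(0, 500, (400, 2))
    types = rng.choice(["E", "T", "U"], 400, p=[0.2, 0.4, 0.4])
    ds = _geo(xy, types)
    d = nearest_effector_distance(ds, "E")
    eff_idx = np.flatnonzero(types == "E")
    for i in range(400):
        others = eff_idx[eff_idx != i]
        expected = np.min(np.linalg.norm(xy[others] - xy[i], axis=1))
        assert d[i] == pytest.approx(expected)


def _toy_line():
    """Effector at x=0; targets at 5, 10, 40, 50, 60 um."""
    xy = [[0, 0], [5, 0], [10, 0], [40, 0], [50, 0], [60, 0]]
    return _geo(xy, ["E", "T", "T", "T", "T", "T"])


def test_label_near_far_farthest_hand_layout():
    labels = label_near_far(_toy_line(), "E", "T", {"all": 20.0})
    tab = labels.table
    assert set(tab.index[tab.label == "Near"]) == {"c1", "c2"}  # 5 and 10 um
    assert set(tab.index[tab.label == "Far"]) == {"c4", "c5"}  # 60 and 50 um
    assert tab.loc["c3", "label"] == "unlabeled"


def test_label_near_far_area_restricted():
    # annulus (7, 20): only the 10 um target is Near
    labels = label_near_far(
        _toy_line(), "E", "T", {"all": 20.0}, area_restricted=True, inner_offset_um=13.0
    )
    tab = labels.table
    assert set(tab.index[tab.label == "Near"]) == {"c2"}
    assert (tab.label == "Far").sum() == 1


def test_label_near_far_random_is_seeded():
    a = label_near_far(_toy_line(), "E", "T", {"all": 20.0}, strategy="random", seed=5)
    b = label_near_far(_toy_line(), "E", "T", {"all": 20.0}, strategy="random", seed=5)
    pd.testing.assert_frame_equal(a.table, b.table)


@pytest.mark.parametrize("strategy", ["farthest", "random", "count_matched"])
@pytest.mark.parametrize("area_restricted", [False, True])
def test_matching_equals_bruteforce(strategy, area_restricted):
    """Exhaustive per-stratum reimplementation of the matching rules."""
    rng = np.random.default_rng(13)
    n = 1000
    xy = rng.uniform(0, 800, (n, 2))
    types = rng.choice(["E", "T", "U"], n, p=[0.08, 0.5, 0.42])
    subr = np.where(xy[:, 0] < 400, "L", "R")
    samples = np.where(xy[:, 1] < 400, "s0", "s1")
    ds = _geo(xy, types, subregions=subr, sample=list(samples))
    ds.X = rng.integers(0, 50, size=ds.shape)
    cutoffs = {"L": 35.0, "R": 28.0}
    labels = label_near_far(
        ds, "E", "T", cutoffs, strategy=strategy,
        area_restricted=area_restricted, inner_offset_um=15.0, seed=99,
    )
    expected: dict[int, str] = {}
    d = nearest_effector_distance(ds, "E")
    rng2 = np.random.default_rng(99)
    obs = ds.obs
    totals = np.asarray(ds.X).sum(axis=1).astype(float)
    t_all = np.flatnonzero((obs["cell_type"] == "T").to_numpy())
    for samp, subr_name in sorted(
        {(str(obs["sample_id"].iloc[i]), str(obs["subregion"].iloc[i])) for i in t_all}
    ):
        cut = cutoffs[subr_name]
        inner = cut - 15.0 if area_restricted else -np.inf
        members = [
            i for i in t_all
            if str(obs["sample_id"].iloc[i]) == samp
            and str(obs["subregion"].iloc[i]) == subr_name
        ]
        near = [i for i in members if inner < d[i] < cut] if area_restricted else [
            i for i in members if d[i] < cut
        ]
        pool = [i for i in members if cut < d[i] < np.inf]
        for i in near:
            expected[i] = "Near"
        if not near or not pool:
            continue
        nsel = min(len(near), len(pool))
        if strategy == "farthest":
            chosen = sorted(pool, key=lambda i: (-d[i], i))[:nsel]
        elif strategy == "random":
            chosen = list(rng2.choice(pool, size=nsel, replace=False))
        else:
            tm = np.mean([totals[i] for i in near])
            chosen = sorted(pool, key=lambda i: (abs(totals[i] - tm), i))[:nsel]
        for i in chosen:
            expected[i] = "Far"
    got = labels.table["label"]
    for i in t_all:
        assert got.loc[ds.obs_names[i]] == expected.get(i, "unlabeled"), ds.obs_names[i]


def test_cohens_d_hand_example():
    assert cohens_d(np.array([1.0, 2.0]), np.array([0.0, 1.0])) == pytest.approx(
        np.sqrt(2), abs=1e-4
    )


def test_cohens_d_is_antisymmetric():
    rng = np.random.default_rng(2)
    a, b = rng.normal(0, 1, 40), rng.normal(0.5, 1, 40)
    assert cohens_d(a, b) == pytest.approx(-cohens_d(b, a))


def test_cohens_d_consistency_large_samples():
    rng = np.random.default_rng(3)
    delta = 0.4
    near = rng.normal(delta, 1, 5000)
    far = rng.normal(0, 1, 5000)
    assert abs(cohens_d(near, far) - delta) < 0.05


def test_proximity_effect_identical_groups_and_filter():
    labels = label_near_far(_toy_line(), "E", "T", {"all": 20.0})
    accel = pd.DataFrame(
        {"age_acceleration": [0.5, 0.5, 0.5, 0.5, 0.5]},
        index=[f"c{i}" for i in range(1, 6)],
    )
    res = proximity_effect(labels, accel, min_group=1)
    assert res.degenerate  # zero pooled variance flagged
    accel["age_acceleration"] = [1.0, 2.0, 0.0, 1.0, 0.0]
    res = proximity_effect(labels, accel, min_group=1)
    assert res.n_near == 2 and res.n_far == 2
    assert res.passes_filter
    res50 = proximity_effect(labels, accel, min_group=50)
    assert not res50.passes_filter
    assert res.normalized_frequency == pytest.approx(2 / 5)


def test_screen_restriction_consistency(ds8):
    rng = np.random.default_rng(4)
    obs = ds8.obs
    accel = pd.DataFrame(
        {
            "cell_type": obs["cell_type"].astype(str).to_numpy(),
            "age_acceleration": rng.normal(0, 1, ds8.n_obs),
        },
        index=obs.index,
    )
    cutoffs = {s: 40.0 for s in obs["subregion"].astype(str).unique()}
    full_restricted, _, _ = spc.proximity_screen(
        ds8, accel, cutoffs, effectors=["T cell"], targets=["Oligodendrocyte"],
        min_group=5, region="CC/ACO",
    )
    subset = ds8[(obs["region"].astype(str) == "CC/ACO").to_numpy()]
    on_subset, _, _ = spc.proximity_screen(
        subset, accel, cutoffs, effectors=["T cell"], targets=["Oligodendrocyte"],
        min_group=5,
    )
    pd.testing.assert_frame_equal(full_restricted, on_subset)


def test_permutation_null_is_reproducible_and_degenerate_case(ds8):
    rng = np.random.default_rng(5)
    accel = pd.DataFrame(
        {
            "cell_type": ds8.obs["cell_type"].astype(str).to_numpy(),
            "age_acceleration": rng.normal(0, 1, ds8.n_obs),
        },
        index=ds8.obs_names,
    )
    cutoffs = {s: 40.0 for s in ds8.obs["subregion"].astype(str).unique()}
    kw = dict(
        effectors=["Microglia"], targets=["Oligodendrocyte"], min_group=5
    )
    n1 = spatial_permutation_null(ds8, accel, cutoffs, n_perm=2, master_seed=444, **kw)
    n2 = spatial_permutation_null(ds8, accel, cutoffs, n_perm=2, master_seed=444, **kw)
    assert n1.seeds == n2.seeds
    pd.testing.assert_frame_equal(n1.ape_per_perm, n2.ape_per_perm)
    one = spatial_permutation_null(ds8, accel, cutoffs, n_perm=1, master_seed=3, **kw)
    summ = one.summary()
    assert summ["median"].iloc[0] == one.ape_per_perm.iloc[0, 0]


def test_signature_score_and_subtype_split(ds8):
    one = signature_score(ds8, [ds8.var_names[0]])
    np.testing.assert_allclose(one, np.asarray(ds8.layers["lognorm"])[:, 0])
    two = signature_score(ds8, list(ds8.var_names[:2]))
    np.testing.assert_allclose(
        two, np.asarray(ds8.layers["lognorm"])[:, :2].sum(axis=1)
    )
    with pytest.raises(ValueError, match="no signature genes"):
        signature_score(ds8, ["not-a-gene"])
    mask = subtype_split(np.arange(10.0), top_fraction=0.5)
    assert mask.sum() == 5
    assert mask[5:].all() and not mask[:5].any()


def test_subtype_split_breaks_ties_by_index():
    mask = subtype_split(np.ones(10), top_fraction=0.3)
    np.testing.assert_array_equal(np.flatnonzero(mask), [0, 1, 2])


def test_levene_brown_forsythe():
    rng = np.random.default_rng(6)
    a = rng.normal(0, 1, 200)
    b = rng.normal(0, 3, 200)
    stat, p = levene_equal_variance(a, b)
    assert p < 0.01
    s0, p0 = levene_equal_variance(a, a)
    assert s0 == pytest.approx(0.0)
    # manual Brown-Forsythe (no trimming effect at these sizes is not assumed;
    # compare against the direct ANOVA-on-|x - median| computation)
    x = np.array([1.0, 2.0, 3.0, 10.0])
    y = np.array([2.0, 2.5, 3.0, 3.5])
    zx = np.abs(x - np.median(x))
    zy = np.abs(y - np.median(y))
    zbar = np.mean(np.concatenate([zx, zy]))
    num = 4 * ((zx.mean() - zbar) ** 2 + (zy.mean() - zbar) ** 2) / (2 - 1)
    den = (np.sum((zx - zx.mean()) ** 2) + np.sum((zy - zy.mean()) ** 2)) / (8 - 2)
    stat_manual = num / den
    stat_pkg, _ = levene_equal_variance(x, y)
    assert stat_pkg == pytest.approx(stat_manual)
    with pytest.raises(ValueError, match="n >= 2"):
        levene_equal_variance([1.0], [1.0, 2.0])


@settings(deadline=None, derandomize=True, max_examples=20)
@given(st.integers(min_value=0, max_value=10**6))
def test_d_antisymmetric_under_label_swap(seed):
    rng = np.random.default_rng(seed)
    near = rng.normal(0, 1, 10)
    far = rng.normal(1, 2, 12)
    assert cohens_d(near, far) == pytest.approx(-cohens_d(far, near), rel=1e-12)
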
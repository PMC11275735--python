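"""Shared fixtures: small synthetic datasets generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import spatialclocks as spc


@pytest.fixture(scope="session")
def truth8():
    """Small null study: 8 ages, 500 cells/section, no planted effects."""
    return spc.default_truth(seed=4, n_ages=8, cells_per_section=500)


@pytest.fixture(scope="session")
def ds8(truth8):
    """Null dataset with volnorm/lognorm/smoothed layers (do not mutate)."""
    ds, _ = spc.generate_dataset(truth8)
    spc.volume_normalize(ds)
    spc.log_normalize(ds)
    spc.smooth_dataset(ds)
    return ds


@pytest.fixture(scope="session")
def null20():
    """Study-scale null dataset: 20 ages x 1 animal, 1200 cells/section."""
    truth = spc.default_truth(seed=21, n_ages=20, cells_per_section=1200)
    ds, _ = spc.generate_dataset(truth)
    spc.volume_normalize(ds)
    spc.log_normalize(ds)
    return ds


def tiny_dataset(n_cells=10, n_genes=5, seed=0, **obs_overrides):
    """Hand-sized valid dataset for I/O and validation tests."""
    rng = np.random.default_rng(seed)
    counts = rng.integers(0, 20, size=(n_cells, n_genes))
    obs = pd.DataFrame(
        {
            "x": rng.uniform(0, 100, n_cells),
            "y": rng.uniform(0, 100, n_cells),
            "volume": rng.uniform(200, 800, n_cells),
            "cell_type": rng.choice(["A", "B"], n_cells),
            "animal_id": np.repeat("m0", n_cells),
            "age_months": 12.0,
        },
        index=[f"c{i}" for i in range(n_cells)],
    )
    for k, vals in obs_overrides.items():
        obs[k] = vals
    return spc.make_dataset(counts, [f"g{j}" for j in range(n_genes)], obs)
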
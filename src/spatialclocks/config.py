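"""Run configuration for the spatialclocks pipeline.

Collects the numerical constants used across the pipeline: the graph
smoothing parameters (alpha, number of neighbours, iteration cap and
tolerance), the lasso clock cross-validation settings, the Near/Far
matching rules of the proximity analysis, and the GIN training
hyper-parameters. Defaults are the values used for the MERFISH brain
aging analysis this package implements.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class SmoothingConfig:
    """SpatialSmooth parameters: X_{t+1} = (1-alpha)X + alpha*S*X_t."""

    alpha: float = 0.8
    k_neighbors: int = 20
    max_iter: int = 30
    tol: float = 0.01  # sup-norm convergence tolerance

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError(f"alpha must be in [0, 1), got {self.alpha}")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


@dataclass
class ClockConfig:
    """Lasso aging-clock training settings (standardize + LassoCV)."""

    cv_folds: int = 5
    n_penalties: int = 20
    max_iter: int = 10000
    group_folds_by_animal: bool = False

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.n_penalties < 1:
            raise ValueError("n_penalties must be >= 1")


@dataclass
class ProximityConfig:
    """Near/Far matching and effect-size settings."""

    min_group: int = 50          # minimum Near and Far counts to keep a pair
    far_strategy: str = "farthest"  # farthest | random | count_matched
    inner_offset_um: float = 15.0   # annulus width offset for area-restricted mode
    welch: bool = False

    def __post_init__(self) -> None:
        if self.min_group < 1:
            raise ValueError("min_group must be >= 1")
        if self.far_strategy not in ("farthest", "random", "count_matched"):
            raise ValueError(f"unknown far_strategy {self.far_strategy!r}")


@dataclass
class GNNConfig:
    """Graph isomorphism network settings for neighborhood-aging regression."""

    hidden_dim: int = 16
    layers: int = 3
    lr: float = 1e-4
    batch_size: int = 64
    epochs: int = 50
    n_bins: int = 10            # label bins for balanced (inverse-frequency) MSE
    prune_um: float = 200.0     # Delaunay edge pruning distance for the global graph
    max_centers: int = 100      # sampled center cells per type per section
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.layers < 1:
            raise ValueError("layers must be >= 1")
        if self.lr <= 0:
            raise ValueError("lr must be > 0")


@dataclass
class RunConfig:
    """Top-level configuration; nested sections mirror the pipeline stages."""

    seed: int = 0
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)
    clock: ClockConfig = field(default_factory=ClockConfig)
    proximity: ProximityConfig = field(default_factory=ProximityConfig)
    gnn: GNNConfig = field(default_factory=GNNConfig)
    paths: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, sub in (
            ("smoothing", SmoothingConfig),
            ("clock", ClockConfig),
            ("proximity", ProximityConfig),
            ("gnn", GNNConfig),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
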
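"""MERFISH-like synthetic data with known generative ground truth.

The generator emulates the documented statistical structure of a brain-wide
spatial transcriptomics aging study: ~18 cell types whose proportions drift
with age (T cells and microglia up, NSCs/OPCs/neuroblasts down), a
subregion-structured spatial layout (white matter, cortex, striatum,
ventricles), per-cell-type gene expression programs that are log-linear in
age, and optional planted effector->target proximity effects that shift the
*effective transcriptomic age* of nearby target cells by a known number of
months.

Counts are negative-binomial with mean

    mu[cell, gene] = volume * baseline[type, gene]
                     * exp(slope[type, gene] * (effective_age - age_ref))

so that a linear model on log-normalized expression is well specified and
clock-recovery tests are sharp. Proximity effects act through the same
expression programs as age (they shift effective age), which is exactly the
construct the aging clocks are meant to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .data_io import CELL_TYPES, make_dataset


@dataclass
class SubregionSpec:
    """A rectangular subregion with its own cell-type mixture multipliers."""

    name: str
    region: str
    rect: tuple[float, float, float, float]  # x0, y0, x1, y1 in microns
    type_weights: np.ndarray  # (n_types,) multipliers on the global mixture

    @property
    def area(self) -> float:
        x0, y0, x1, y1 = self.rect
        return (x1 - x0) * (y1 - y0)


@dataclass
class EffectorRule:
    """Planted proximity effect: targets within ``radius_um`` of an effector
    cell get ``delta_months`` added to their effective transcriptomic age."""

    effector_type: str
    target_types: tuple[str, ...] | None  # None = all types
    radius_um: float
    delta_months: float

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("radius_um must be > 0")


@dataclass
class SyntheticTruth:
    """Full generative parameter set; fixed by ``seed`` for reproducibility."""

    ages: np.ndarray
    n_animals_per_age: int
    cells_per_section: int
    cell_types: tuple[str, ...]
    base_props: np.ndarray            # (T,)
    prop_slopes: np.ndarray           # (T,) per month
    subregions: list[SubregionSpec]
    gene_names: tuple[str, ...]
    baseline_mean: np.ndarray         # (T, G) counts per um^3
    age_slope: np.ndarray             # (T, G) log-mean change per month
    dispersion: float                 # NB shape (theta); larger = closer to Poisson
    volume_log_mu: float              # lognormal volume model
    volume_log_sigma: float
    effector_rules: list[EffectorRule] = field(default_factory=list)
    seed: int = 0

    @property
    def age_ref(self) -> float:
        return float(np.mean(self.ages))

    def validate(self) -> None:
        ages = np.asarray(self.ages, float)
        if not np.all(np.diff(ages) > 0):
            raise ValueError("ages must be strictly increasing")
        for rule in self.effector_rules:
            if rule.effector_type not in self.cell_types:
                raise ValueError(f"unknown effector type {rule.effector_type!r}")
        # proportions must be non-negative at the extreme ages in every subregion
        for age in (ages[0], ages[-1]):
            raw = self.base_props + self.prop_slopes * (age - self.age_ref)
            if np.any(raw < 0):
                bad = [self.cell_types[i] for i in np.flatnonzero(raw < 0)]
                raise ValueError(f"infeasible proportions at age {age}: {bad}")

    def subregion_props(self, age: float) -> np.ndarray:
        """(S, T) cell-type proportions per subregion at a given age."""
        raw = self.base_props + self.prop_slopes * (age - self.age_ref)
        raw = np.clip(raw, 0.0, None)
        out = np.stack([s.type_weights * raw for s in self.subregions])
        return out / out.sum(axis=1, keepdims=True)

    def expected_proportions(self, age: float) -> np.ndarray:
        """Marginal (area-weighted) cell-type proportions at a given age."""
        areas = np.array([s.area for s in self.subregions], float)
        areas /= areas.sum()
        return areas @ self.subregion_props(age)


def _default_subregions(n_types: int, types: tuple[str, ...]) -> list[SubregionSpec]:
    idx = {t: i for i, t in enumerate(types)}

    def weights(**mult: float) -> np.ndarray:
        w = np.ones(n_types)
        for t, m in mult.items():
            key = t.replace("_", " ").replace("Neuron ", "Neuron-")
            w[idx[key]] = m
        return w

    return [
        SubregionSpec(
            "CC/ACO", "CC/ACO", (0.0, 0.0, 750.0, 750.0),
            weights(Oligodendrocyte=4.0, OPC=2.0, Microglia=1.5, **{
                "Neuron_Excitatory": 0.2, "Neuron_Inhibitory": 0.3, "Neuron_MSN": 0.1,
                "T cell": 2.0,
            }),
        ),
        SubregionSpec(
            "CTX_L4/5/6", "CTX", (750.0, 0.0, 1500.0, 750.0),
            weights(**{"Neuron_Excitatory": 2.2, "Neuron_Inhibitory": 1.5,
                       "Neuron_MSN": 0.1, "Oligodendrocyte": 0.5, "NSC": 0.1,
                       "Neuroblast": 0.1, "Ependymal": 0.1}),
        ),
        SubregionSpec(
            "STR_CP/ACB", "STR", (0.0, 750.0, 750.0, 1500.0),
            weights(**{"Neuron_MSN": 3.5, "Neuron_Excitatory": 0.3, "NSC": 0.2,
                       "Ependymal": 0.2}),
        ),
        SubregionSpec(
            "VEN", "VEN", (750.0, 750.0, 1500.0, 1500.0),
            weights(NSC=8.0, Neuroblast=6.0, Ependymal=8.0, Microglia=1.2, **{
                "Neuron_Excitatory": 0.3, "Neuron_MSN": 0.3, "T cell": 2.0}),
        ),
    ]


def default_truth(
    seed: int = 0,
    n_ages: int = 20,
    age_range: tuple[float, float] = (3.4, 34.2),
    n_animals_per_age: int = 1,
    cells_per_section: int = 2000,
    n_genes: int = 300,
    n_age_genes: int = 50,
    age_slope_magnitude: float = 0.04,
    dispersion: float = 20.0,
    effector_rules: list[EffectorRule] | None = None,
    cell_type_boost: dict[str, float] | None = None,
) -> SyntheticTruth:
    """Construct the default study conditions.

    Defaults mirror the documented scale of the source study: 20 ages tiling
    the mouse lifespan, a 300-gene panel of which 50 genes per cell type
    carry age programs (slope +-0.04 per month on the log NB mean), 18 cell
    types with aging proportion trends, and four subregions on a 1.5 mm
    square section at ~1 cell / (27 um)^2 density.

    ``cell_type_boost`` multiplies selected base proportions (renormalized);
    used to make rare effector types abundant enough for planted-effect
    scenarios.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA61]))
    types = CELL_TYPES
    T = len(types)
    base = np.array([
        0.22,   # Neuron-Excitatory
        0.10,   # Neuron-Inhibitory
        0.08,   # Neuron-MSN
        0.13,   # Astrocyte
        0.15,   # Oligodendrocyte
        0.05,   # OPC
        0.06,   # Microglia
        0.07,   # Endothelial
        0.02,   # Pericyte
        0.012,  # VSMC
        0.012,  # VLMC
        0.02,   # Ependymal
        0.025,  # NSC
        0.025,  # Neuroblast
        0.01,   # Macrophage
        0.008,  # T cell
        0.004,  # B cell
        0.004,  # Neutrophil
    ])
    slopes = np.zeros(T)
    tidx = {t: i for i, t in enumerate(types)}
    slopes[tidx["Microglia"]] = +8e-4
    slopes[tidx["Oligodendrocyte"]] = +1e-3
    slopes[tidx["T cell"]] = +4e-4
    slopes[tidx["OPC"]] = -8e-4
    slopes[tidx["NSC"]] = -8e-4
    slopes[tidx["Neuroblast"]] = -8e-4
    if cell_type_boost:
        for t, m in cell_type_boost.items():
            base[tidx[t]] *= m
            slopes[tidx[t]] *= m
    base /= base.sum()

    genes = tuple(f"g{i + 1:03d}" for i in range(n_genes))
    # baseline densities give ~400 total counts for a median 500 um^3 cell
    b0 = 400.0 / (n_genes * 500.0)
    baseline = np.exp(rng.normal(np.log(b0), 0.8, size=(T, n_genes)))
    slope_mat = np.zeros((T, n_genes))
    for t in range(T):
        informative = rng.choice(n_genes, size=n_age_genes, replace=False)
        signs = np.where(np.arange(n_age_genes) % 2 == 0, 1.0, -1.0)
        slope_mat[t, informative] = signs * age_slope_magnitude

    truth = SyntheticTruth(
        ages=np.round(np.linspace(*age_range, n_ages), 1),
        n_animals_per_age=n_animals_per_age,
        cells_per_section=cells_per_section,
        cell_types=types,
        base_props=base,
        prop_slopes=slopes,
        subregions=_default_subregions(T, types),
        gene_names=genes,
        baseline_mean=baseline,
        age_slope=slope_mat,
        dispersion=dispersion,
        volume_log_mu=float(np.log(500.0)),
        volume_log_sigma=0.35,
        effector_rules=list(effector_rules or []),
        seed=seed,
    )
    truth.validate()
    return truth


def _effective_ages(
    xy: np.ndarray,
    cell_types: np.ndarray,
    age: float,
    rules: list[EffectorRule],
    delta_override: dict[str, float] | None = None,
) -> np.ndarray:
    """Chronological age plus the sum of applicable effector-rule deltas.

    A cell of the effector type never counts as its own effector (distance
    to *another* effector is used), matching the proximity analysis.
    """
    eff = np.full(len(xy), float(age))
    for rule in rules:
        is_eff = cell_types == rule.effector_type
        n_eff = int(is_eff.sum())
        if n_eff == 0:
            continue
        tree = cKDTree(xy[is_eff])
        if rule.target_types is None:
            targets = np.ones(len(xy), bool)
        else:
            targets = np.isin(cell_types, rule.target_types)
        t_xy = xy[targets]
        t_is_eff = is_eff[targets]
        dist = np.full(len(t_xy), np.inf)
        non_self = ~t_is_eff
        if non_self.any():
            dist[non_self], _ = tree.query(t_xy[non_self], k=1)
        if t_is_eff.any() and n_eff >= 2:
            d2, _ = tree.query(t_xy[t_is_eff], k=2)
            dist[t_is_eff] = d2[:, 1]
        hit = np.zeros(len(xy), bool)
        hit[np.flatnonzero(targets)[dist < rule.radius_um]] = True
        eff[hit] += rule.delta_months
    if delta_override:
        for ctype, delta in delta_override.items():
            eff[cell_types == ctype] += delta
    return eff


def _generate_section(
    truth: SyntheticTruth,
    age: float,
    rng: np.random.Generator,
    delta_override: dict[str, float] | None = None,
):
    n = truth.cells_per_section
    areas = np.array([s.area for s in truth.subregions])
    n_per_sub = rng.multinomial(n, areas / areas.sum())
    props = truth.subregion_props(age)

    sub_names, regions, xs, ys, type_arr = [], [], [], [], []
    for s_i, (sub, n_s) in enumerate(zip(truth.subregions, n_per_sub)):
        counts = rng.multinomial(n_s, props[s_i])
        t_idx = np.repeat(np.arange(len(truth.cell_types)), counts)
        rng.shuffle(t_idx)
        x0, y0, x1, y1 = sub.rect
        xs.append(rng.uniform(x0, x1, n_s))
        ys.append(rng.uniform(y0, y1, n_s))
        type_arr.append(t_idx)
        sub_names += [sub.name] * n_s
        regions += [sub.region] * n_s
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    t_idx = np.concatenate(type_arr)
    ctypes = np.asarray(truth.cell_types, dtype=object)[t_idx]

    volume = rng.lognormal(truth.volume_log_mu, truth.volume_log_sigma, n)
    eff_age = _effective_ages(
        np.column_stack([x, y]), ctypes, age, truth.effector_rules, delta_override
    )
    log_mu = (
        np.log(truth.baseline_mean[t_idx])
        + truth.age_slope[t_idx] * (eff_age - truth.age_ref)[:, None]
        + np.log(volume)[:, None]
    )
    mu = np.exp(log_mu)
    lam = rng.gamma(truth.dispersion, mu / truth.dispersion)
    counts = rng.poisson(lam).astype(np.int64)
    obs = pd.DataFrame(
        {
            "x": x,
            "y": y,
            "volume": volume,
            "cell_type": ctypes.astype(str),
            "age_months": float(age),
            "subregion": sub_names,
            "region": regions,
            "effective_age": eff_age,
        }
    )
    return counts, obs


def generate_dataset(
    truth: SyntheticTruth,
    condition: str = "control",
    delta_override: dict[str, float] | None = None,
    seed_offset: int = 0,
) -> tuple[ad.AnnData, pd.Series]:
    """Sample a full multi-animal dataset from the generative model.

    Returns the dataset and the per-cell effective transcriptomic age (also
    stored as ``obs["effective_age"]``). Identical ``truth`` (same seed)
    gives byte-identical output.
    """
    truth.validate()
    if delta_override:
        unknown = set(delta_override) - set(truth.cell_types)
        if unknown:
            raise ValueError(f"unknown cell types in delta map: {sorted(unknown)}")
    blocks = []
    for a_i, age in enumerate(np.asarray(truth.ages, float)):
        for rep in range(truth.n_animals_per_age):
            rng = np.random.default_rng(
                np.random.SeedSequence([truth.seed, seed_offset, a_i, rep])
            )
            counts, obs = _generate_section(truth, age, rng, delta_override)
            animal = f"{condition}_a{a_i:02d}r{rep}"
            obs["animal_id"] = animal
            obs["sample_id"] = animal  # one section per animal
            obs.index = [f"{animal}_c{i:05d}" for i in range(len(obs))]
            blocks.append((counts, obs))
    counts = np.vstack([c for c, _ in blocks])
    obs = pd.concat([o for _, o in blocks])
    obs["condition"] = condition
    adata = make_dataset(counts, list(truth.gene_names), obs)
    return adata, adata.obs["effective_age"].copy()


def generate_condition_pair(
    truth: SyntheticTruth,
    intervention_delta_months: dict[str, float],
) -> tuple[ad.AnnData, ad.AnnData]:
    """Generate a matched control / intervention pair of datasets.

    Both arms share all generative parameters; in the intervention arm,
    cells of the listed types have their effective age shifted by the stated
    delta (months) before expression is sampled. Arms use disjoint animals
    (independent draws), emulating a two-arm animal experiment.
    """
    control, _ = generate_dataset(truth, condition="control", seed_offset=101)
    intervention, _ = generate_dataset(
        truth,
        condition="intervention",
        delta_override=intervention_delta_months,
        seed_offset=202,
    )
    return control, intervention


# ---------------------------------------------------------------------------
# local-graph fixtures for the GNN module


@dataclass
class CountingRule:
    """Maps a graph's cell-type composition to a scalar label:
    ``label = sum_t weight[t] * count(t) + intercept + Normal(0, noise_sd)``."""

    weights: dict[str, float]
    intercept: float = 0.0
    noise_sd: float = 0.0

    def label(self, type_names: np.ndarray, rng: np.random.Generator) -> float:
        lab = self.intercept + sum(
            w * int(np.sum(type_names == t)) for t, w in self.weights.items()
        )
        if self.noise_sd > 0:
            lab += rng.normal(0.0, self.noise_sd)
        return float(lab)


def generate_local_graph_fixtures(
    n_graphs: int,
    rule: CountingRule,
    seed: int = 0,
    n_nodes_range: tuple[int, int] = (5, 60),
    vocabulary: tuple[str, ...] = CELL_TYPES,
    type_probs: np.ndarray | None = None,
):
    """Random connected local cell graphs with labels computed by ``rule``.

    Each graph is a random tree plus extra random edges (connected by
    construction), nodes carry cell types drawn i.i.d. from ``type_probs``
    (uniform by default), and the center is a random node. Returns
    ``(graphs, rule)`` so tests can recompute labels independently.
    """
    from .gnn import LocalCellGraph  # local import to avoid a hard dependency cycle

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x617]))
    if type_probs is None:
        type_probs = np.full(len(vocabulary), 1.0 / len(vocabulary))
    graphs = []
    lo, hi = n_nodes_range
    for g in range(n_graphs):
        n = int(rng.integers(lo, hi + 1))
        edges = set()
        for v in range(1, n):  # random tree: attach each node to a prior node
            u = int(rng.integers(0, v))
            edges.add((min(u, v), max(u, v)))
        for _ in range(int(rng.integers(0, n))):  # extra edges
            u, v = rng.integers(0, n, 2)
            if u != v:
                edges.add((min(u, v), max(u, v)))
        t_idx = rng.choice(len(vocabulary), size=n, p=type_probs)
        type_names = np.asarray(vocabulary, dtype=object)[t_idx]
        label = rule.label(type_names, rng)
        graphs.append(
            LocalCellGraph(
                node_types=t_idx.astype(np.int64),
                edges=np.array(sorted(edges), dtype=np.int64).reshape(-1, 2),
                center=int(rng.integers(0, n)),
                label=label,
                vocabulary=tuple(vocabulary),
                provenance=("fixture", f"graph{g}"),
            )
        )
    return graphs, rule
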
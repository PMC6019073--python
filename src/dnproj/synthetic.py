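"""Synthetic catalogs and volumes with planted, known ground truth.

The generator emulates the coarse statistical architecture of the fly
descending-neuron projectome: a handful of pathway classes, each linking a
small set of brain input neuropils to a set of VNC output neuropils —
a dorsal-direct class (posterior slope IPS/SPS to neck/wing/haltere), a
leg-direct class (GNG to the three leg neuromeres), a convergent class
(broadly distributed brain sources onto the tectulum), and an unstructured
remainder.  Within a class, innervation is Bernoulli: probability ``p_in``
on the class's block, ``p_bg`` elsewhere.  Laterality, tract use, and the
unique/population split are drawn from configured marginals.

Every draw comes from per-class substreams spawned from one seed in a fixed
order, so adding a pathway class never perturbs records generated by
earlier classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .catalog import (
    DNCatalog,
    DNRecord,
    Polarity,
    load_default_atlases,
)
from .cluster import average_linkage, correlation_distance_matrix, cut_dendrogram
from .matrix import build_matrix
from .pathways import aggregate_by_group, connectivity_matrix

__all__ = [
    "PathwaySpec",
    "GeneratorConfig",
    "PlantedTruth",
    "default_config",
    "recovery_config",
    "generate_catalog",
    "generate_voxel_mask",
    "recovery_score",
    "planted_clustering_recovery",
    "planted_pathway_recovery",
]

_BROAD_BRAIN_POOL = (
    "AVLP", "PVLP", "PLP", "LAL", "VES", "SMP", "AMMC", "SAD", "WED", "GOR",
    "EPA", "BU", "AL", "SLP", "ICL", "IB",
)


@dataclass(frozen=True)
class PathwaySpec:
    """One planted pathway class of the generator."""

    name: str
    n_types: int
    brain_sources: tuple[str, ...]
    vnc_targets: tuple[str, ...]
    p_in: float = 0.9
    p_bg: float = 0.05
    #: For convergent-style classes: number of brain sources drawn per type
    #: from ``brain_sources`` (None = use the whole set for every type).
    source_breadth: int | None = None
    soma_group_weights: dict[str, float] = field(default_factory=lambda: {"p": 1.0})
    tract_weights: dict[str, float] = field(default_factory=lambda: {"MTD": 1.0})

    def __post_init__(self) -> None:
        if not (0 <= self.p_in <= 1 and 0 <= self.p_bg <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.n_types < 0:
            raise ValueError("n_types must be >= 0")
        if self.n_types > 0 and (not self.brain_sources or not self.vnc_targets):
            raise ValueError(
                f"pathway {self.name!r}: positive n_types with empty source/target set"
            )


@dataclass(frozen=True)
class GeneratorConfig:
    pathways: tuple[PathwaySpec, ...]
    population_fraction: float = 0.2
    pair_count_range: tuple[int, int] = (2, 10)  # inclusive, population types
    ipsilateral_p: float = 0.64

    def __post_init__(self) -> None:
        if not 0 <= self.population_fraction <= 1:
            raise ValueError("population_fraction must be in [0, 1]")
        if not 0 <= self.ipsilateral_p <= 1:
            raise ValueError("ipsilateral_p must be in [0, 1]")


@dataclass
class PlantedTruth:
    """Ground-truth pathway membership for every generated type."""

    pathway: dict[str, str]  # type_id -> pathway class name

    def labels_for(self, type_ids: list[str]) -> list[str]:
        return [self.pathway[t] for t in type_ids]


def default_config() -> GeneratorConfig:
    """Study-scale defaults: ~98 types, three planted pathways, 64% ipsilateral."""
    return GeneratorConfig(
        pathways=(
            PathwaySpec(
                "dorsal_direct", 30,
                brain_sources=("IPS", "SPS"),
                vnc_targets=("neck", "wing", "haltere"),
                soma_group_weights={"p": 0.7, "a": 0.1, "b": 0.1, "c": 0.05, "d": 0.05},
                tract_weights={"MTD": 0.6, "ITD": 0.2, "DLT": 0.1, "MDA": 0.1},
            ),
            PathwaySpec(
                "leg_direct", 30,
                brain_sources=("GNG",),
                vnc_targets=("foreleg", "middle_leg", "hindleg"),
                soma_group_weights={"g": 0.8, "p": 0.1, "b": 0.1},
                tract_weights={"ITD": 0.4, "MTD": 0.2, "VLT": 0.2, "VTV": 0.2},
            ),
            PathwaySpec(
                "convergent", 20,
                brain_sources=_BROAD_BRAIN_POOL,
                vnc_targets=("tectulum", "lower_tectulum"),
                source_breadth=6,
                soma_group_weights={"p": 0.4, "g": 0.3, "a": 0.2, "c": 0.1},
                tract_weights={"MTD": 0.3, "ITD": 0.3, "DLV": 0.2, "VTV": 0.2},
            ),
            PathwaySpec(
                "other", 18,
                brain_sources=_BROAD_BRAIN_POOL,
                vnc_targets=("AMN", "AS", "VAC", "mVAC", "wing", "foreleg"),
                p_in=0.3,
                source_breadth=3,
                soma_group_weights={"a": 0.2, "b": 0.2, "c": 0.2, "d": 0.2, "p": 0.2},
                tract_weights={"DLT": 0.25, "MDA": 0.25, "DLV": 0.25, "other": 0.25},
            ),
        ),
    )


def recovery_config(
    n_dorsal: int = 30, n_leg: int = 30, p_in: float = 0.9, p_bg: float = 0.05
) -> GeneratorConfig:
    """Two direct pathways only — the planted-recovery benchmark condition."""
    base = default_config()
    dorsal = replace(base.pathways[0], n_types=n_dorsal, p_in=p_in, p_bg=p_bg)
    leg = replace(base.pathways[1], n_types=n_leg, p_in=p_in, p_bg=p_bg)
    return GeneratorConfig(pathways=(dorsal, leg))


def _weighted_choice(rng: np.random.Generator, weights: dict[str, float]) -> str:
    keys = sorted(weights)
    p = np.array([weights[k] for k in keys], dtype=float)
    p = p / p.sum()
    return keys[rng.choice(len(keys), p=p)]


def generate_catalog(
    config: GeneratorConfig, seed: int
) -> tuple[DNCatalog, PlantedTruth]:
    """Draw a catalog with planted pathway structure; reproducible given seed.

    Type names are assigned per soma group with sequential two-digit
    indices; a configuration needing more than 99 types in one soma group
    is infeasible under the nomenclature grammar and raises.
    """
    brain_atlas, vnc_atlas = load_default_atlases()
    streams = np.random.SeedSequence(seed).spawn(len(config.pathways))
    drafts: list[dict] = []
    truth: dict[str, str] = {}
    for spec, ss in zip(config.pathways, streams):
        rng = np.random.default_rng(ss)
        for _ in range(spec.n_types):
            soma = _weighted_choice(rng, spec.soma_group_weights)
            if spec.source_breadth is not None:
                k = min(spec.source_breadth, len(spec.brain_sources))
                sources = set(
                    np.array(spec.brain_sources)[
                        rng.choice(len(spec.brain_sources), size=k, replace=False)
                    ]
                )
            else:
                sources = set(spec.brain_sources)
            brain_ann = {}
            for a in brain_atlas.abbreviations:
                p = spec.p_in if a in sources else spec.p_bg
                if rng.random() < p:
                    brain_ann[a] = Polarity("smooth")
            vnc_ann = {}
            targets = set(spec.vnc_targets)
            for a in vnc_atlas.abbreviations:
                p = spec.p_in if a in targets else spec.p_bg
                if rng.random() < p:
                    vnc_ann[a] = Polarity("varicose")
            is_pop = rng.random() < config.population_fraction
            lo, hi = config.pair_count_range
            n_pairs = int(rng.integers(lo, hi + 1)) if is_pop else 1
            lat = "ipsilateral" if rng.random() < config.ipsilateral_p else "contralateral"
            tract = _weighted_choice(rng, spec.tract_weights)
            drafts.append(
                dict(
                    pathway=spec.name,
                    soma_group=soma,
                    kind="population" if is_pop else "unique",
                    n_pairs=n_pairs,
                    laterality=lat,
                    tract=tract,
                    brain_innervation=brain_ann,
                    vnc_innervation=vnc_ann,
                )
            )
    counters: dict[str, int] = {}
    records = []
    for d in drafts:
        g = d["soma_group"]
        counters[g] = counters.get(g, 0) + 1
        if counters[g] > 99:
            raise ValueError(
                f"soma group {g!r} needs more than 99 types; the two-digit "
                "nomenclature cannot accommodate this configuration"
            )
        type_id = f"DN{g}{counters[g]:02d}"
        pathway = d.pop("pathway")
        records.append(DNRecord(type_id=type_id, **d))
        truth[type_id] = pathway
    catalog = DNCatalog(
        records, brain_atlas, vnc_atlas, provenance=f"synthetic seed={seed}"
    )
    return catalog, PlantedTruth(truth)


def generate_voxel_mask(
    centroid_um: float,
    spread_um: float,
    n_voxels: int,
    shape: tuple[int, int, int] = (64, 48, 48),
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0),
    soma: tuple[float, int] | None = None,
    axon: tuple[float, int] | None = None,
    seed: int = 0,
):
    """Synthetic labeled volume with neurite voxels planted around a centroid.

    Axis-0 positions are drawn from a normal at ``centroid_um`` with SD
    ``spread_um``, truncated to the volume, and rounded to the nearest
    voxel; the other two coordinates are uniform.  ``soma``/``axon`` are
    optional ``(centroid_um, n_voxels)`` blobs written with their own
    labels so exclusion logic can be exercised.
    """
    from .axis import VoxelMask

    if spread_um < 0:
        raise ValueError("spread must be >= 0")
    depth = shape[0]
    capacity = depth * shape[1] * shape[2]
    total = n_voxels + (soma[1] if soma else 0) + (axon[1] if axon else 0)
    if total > capacity // 2:
        raise ValueError("volume too small for the requested voxel count")
    rng = np.random.default_rng(seed)
    labels = np.zeros(shape, dtype=np.int64)
    occupied: set[tuple[int, int, int]] = set()

    def place(n: int, c_um: float, s_um: float, label: int) -> None:
        sz = voxel_size_um[0]
        placed = 0
        while placed < n:
            if s_um == 0:
                z = int(round(c_um / sz))
            else:
                z = int(round(rng.normal(c_um, s_um) / sz))
            if not 0 <= z < depth:
                continue
            y = int(rng.integers(shape[1]))
            x = int(rng.integers(shape[2]))
            if (z, y, x) in occupied:
                continue
            occupied.add((z, y, x))
            labels[z, y, x] = label
            placed += 1

    place(n_voxels, centroid_um, spread_um, 1)
    if soma is not None:
        place(soma[1], soma[0], 1.0, 2)
    if axon is not None:
        place(axon[1], axon[0], 1.0, 3)
    return VoxelMask(labels, voxel_size_um)


def recovery_score(predicted, truth) -> float:
    """Adjusted Rand index between a predicted partition and the planted truth.

    Computed from the contingency table: with ``n_ij`` the cell counts,
    ``a_i``/``b_j`` the marginals and pairs ``C(x, 2)``,
    ``ARI = (Σ C(n_ij,2) − E) / (max − E)`` where
    ``E = Σ C(a_i,2) Σ C(b_j,2) / C(n,2)`` and
    ``max = (Σ C(a_i,2) + Σ C(b_j,2)) / 2``.
    Accepts two aligned label sequences, or two dicts over the same keys.
    """
    if isinstance(predicted, dict) or isinstance(truth, dict):
        pk = predicted if isinstance(predicted, dict) else None
        tk = truth.pathway if isinstance(truth, PlantedTruth) else truth
        if pk is None or not isinstance(tk, dict):
            raise ValueError("mixed dict/sequence inputs not supported")
        if set(pk) != set(tk):
            raise ValueError("partitions cover different label universes")
        keys = sorted(pk)
        predicted = [pk[k] for k in keys]
        truth = [tk[k] for k in keys]
    predicted = list(predicted)
    truth = list(truth)
    if len(predicted) != len(truth):
        raise ValueError("partitions must label the same items")
    n = len(predicted)
    table: dict[tuple, int] = {}
    a: dict = {}
    b: dict = {}
    for p, t in zip(predicted, truth):
        table[(p, t)] = table.get((p, t), 0) + 1
        a[p] = a.get(p, 0) + 1
        b[t] = b.get(t, 0) + 1
    index = sum(math.comb(v, 2) for v in table.values())
    sum_a = sum(math.comb(v, 2) for v in a.values())
    sum_b = sum(math.comb(v, 2) for v in b.values())
    expected = sum_a * sum_b / math.comb(n, 2)
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return (index - expected) / (max_index - expected)


def planted_clustering_recovery(catalog: DNCatalog, truth: PlantedTruth) -> float:
    """ARI of cut-k=2 average-linkage clustering of the VNC-output matrix.

    Runs the full pipeline — varicose VNC innervation matrix, correlation
    distance over DN-type rows, average linkage, two-cluster cut — and
    scores it against the planted pathway labels.  Types with degenerate
    (zero-variance) profiles are excluded from both partitions.
    """
    m = build_matrix(catalog, catalog.vnc_atlas, "varicose", side="vnc")
    dist = correlation_distance_matrix(m, axis="rows", degenerate="exclude")
    dend = average_linkage(dist)
    flat = cut_dendrogram(dend, k=2)
    return recovery_score(flat, truth.labels_for(dist.labels))


def planted_pathway_recovery(catalog: DNCatalog, truth: PlantedTruth) -> bool:
    """Do the two largest (brain group -> VNC group) blocks match the planted
    direct pathways (posterior slope -> dorsal, GNG -> leg)?"""
    C = connectivity_matrix(catalog)
    agg = aggregate_by_group(C, catalog)
    flat = agg.stack().sort_values(ascending=False)
    top2 = {tuple(ix) for ix in flat.index[:2]}
    return top2 == {("dorsal", "ventromedial_neuropils"), ("leg", "gnathal")}
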
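"""Brain-to-VNC bipartite connectivity and descending-pathway ranking.

The connectivity matrix counts, for every (brain neuropil, VNC neuropil)
pair, how many DN types (or pair-weighted cells) have an input-type process
in the brain neuropil AND an output-type process in the VNC neuropil.
Grouped input/output maps are its rows and columns; rankings and a
normalized-entropy convergence index summarize the dominant pathways.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import DNCatalog
from .matrix import build_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "ConnectivityMatrix",
    "PathwayRanking",
    "connectivity_matrix",
    "group_counts_by_target",
    "group_counts_by_source",
    "rank_pathways",
    "convergence_index",
    "aggregate_by_group",
    "tract_distribution",
    "write_connectivity",
]


@dataclass
class ConnectivityMatrix:
    """VNC-neuropil (rows) x brain-neuropil (columns) DN counts."""

    values: pd.DataFrame  # index = VNC labels, columns = brain labels
    weighting: str
    brain_filter: str
    vnc_filter: str

    @property
    def vnc_labels(self) -> list[str]:
        return list(self.values.index)

    @property
    def brain_labels(self) -> list[str]:
        return list(self.values.columns)

    def row(self, vnc_neuropil: str) -> pd.Series:
        return self.values.loc[vnc_neuropil]

    def col(self, brain_neuropil: str) -> pd.Series:
        return self.values[brain_neuropil]


def connectivity_matrix(
    catalog: DNCatalog,
    brain_filter: str = "smooth",
    vnc_filter: str = "varicose",
    weighting: str = "types",
) -> ConnectivityMatrix:
    """Count DNs linking each brain neuropil to each VNC neuropil.

    Defaults follow the scoring convention for descending information flow:
    smooth (input) processes on the brain side, varicose (output) processes
    on the VNC side.  ``weighting='cells'`` weights each type by its number
    of bilateral pairs.
    """
    if weighting not in ("types", "cells"):
        raise ValueError(f"unknown weighting {weighting!r}")
    bm = build_matrix(catalog, catalog.brain_atlas, brain_filter, side="brain")
    vm = build_matrix(catalog, catalog.vnc_atlas, vnc_filter, side="vnc")
    w = np.array(
        [catalog.get(t).n_pairs if weighting == "cells" else 1 for t in bm.rows],
        dtype=int,
    )
    # counts[v, b] = sum_i w_i * vm[i, v] * bm[i, b]
    counts = (vm.values * w[:, None]).T @ bm.values
    df = pd.DataFrame(counts, index=vm.cols, columns=bm.cols, dtype=int)
    return ConnectivityMatrix(df, weighting, brain_filter, vnc_filter)


def group_counts_by_target(
    catalog: DNCatalog,
    vnc_neuropil: str,
    brain_filter: str = "smooth",
    vnc_filter: str = "varicose",
    weighting: str = "types",
) -> pd.Series:
    """Brain innervation counts of the DNs that output to one VNC neuropil.

    Equals the corresponding row of :func:`connectivity_matrix`.
    """
    if vnc_neuropil not in catalog.vnc_atlas:
        raise KeyError(f"unknown VNC neuropil {vnc_neuropil!r}")
    C = connectivity_matrix(catalog, brain_filter, vnc_filter, weighting)
    return C.row(vnc_neuropil)


def group_counts_by_source(
    catalog: DNCatalog,
    brain_neuropil: str,
    brain_filter: str = "smooth",
    vnc_filter: str = "varicose",
    weighting: str = "types",
) -> pd.Series:
    """VNC projection counts of the DNs with input in one brain neuropil."""
    if brain_neuropil not in catalog.brain_atlas:
        raise KeyError(f"unknown brain neuropil {brain_neuropil!r}")
    C = connectivity_matrix(catalog, brain_filter, vnc_filter, weighting)
    return C.col(brain_neuropil)


@dataclass
class PathwayRanking:
    """(brain neuropil, VNC neuropil, count) triples, largest count first."""

    triples: list[tuple[str, str, int]]

    def __iter__(self):
        return iter(self.triples)

    def __len__(self) -> int:
        return len(self.triples)


def rank_pathways(C: ConnectivityMatrix, top_n: int | None = None) -> PathwayRanking:
    """Rank nonzero (brain, VNC) connections by count, descending.

    Ties are broken by (brain, vnc) label order for determinism.
    """
    if top_n is not None and top_n < 1:
        raise ValueError("top_n must be >= 1")
    triples = [
        (b, v, int(C.values.at[v, b]))
        for b in C.brain_labels
        for v in C.vnc_labels
        if C.values.at[v, b] > 0
    ]
    triples.sort(key=lambda t: (-t[2], t[0], t[1]))
    if top_n is not None:
        triples = triples[:top_n]
    return PathwayRanking(triples)


def convergence_index(C: ConnectivityMatrix, vnc_neuropil: str) -> float:
    """Normalized entropy of the brain-source distribution for one VNC target.

    0 means a single brain source feeds the target; 1 means the sources are
    uniform over every brain compartment with any nonzero count in the
    matrix.  Natural log, with 0*log(0) = 0.
    """
    row = C.row(vnc_neuropil).to_numpy(dtype=float)
    total = row.sum()
    if total <= 0:
        raise ValueError(f"no DNs project to {vnc_neuropil!r}")
    active = int((C.values.sum(axis=0) > 0).sum())
    if active < 2:
        return 0.0
    p = row[row > 0] / total
    H = float(-(p * np.log(p)).sum())
    return H / np.log(active)


def aggregate_by_group(C: ConnectivityMatrix, catalog: DNCatalog) -> pd.DataFrame:
    """Sum connectivity counts into (VNC group) x (brain group) blocks."""
    vg = pd.Series({a: catalog.vnc_atlas.group(a) for a in C.vnc_labels})
    bg = pd.Series({a: catalog.brain_atlas.group(a) for a in C.brain_labels})
    return C.values.groupby(vg).sum().T.groupby(bg).sum().T


def tract_distribution(
    catalog: DNCatalog,
    group_by: str = "none",
    vnc_filter: str = "varicose",
) -> pd.DataFrame | pd.Series:
    """Pair-weighted DN counts per descending tract.

    With ``group_by='vnc_group'`` returns a tract x VNC-target-group
    cross-tabulation; a DN targeting several groups is counted in each
    (logged), so column totals may exceed the catalog's cell count.
    Unknown tracts are tallied under their own ``unknown`` row.
    """
    if group_by == "none":
        counts: dict[str, int] = {}
        for rec in catalog.records:
            counts[rec.tract] = counts.get(rec.tract, 0) + rec.n_pairs
        return pd.Series(counts, dtype=int).sort_index()
    if group_by != "vnc_group":
        raise ValueError(f"unknown group_by {group_by!r}")
    vm = build_matrix(catalog, catalog.vnc_atlas, vnc_filter, side="vnc")
    groups = sorted(set(catalog.vnc_atlas.group(a) for a in vm.cols))
    tracts = sorted({r.tract for r in catalog.records})
    out = pd.DataFrame(0, index=tracts, columns=groups, dtype=int)
    multi = 0
    for i, rec in enumerate(catalog.records):
        hit_groups = {
            catalog.vnc_atlas.group(a)
            for j, a in enumerate(vm.cols)
            if vm.values[i, j]
        }
        if len(hit_groups) > 1:
            multi += 1
        for g in hit_groups:
            out.at[rec.tract, g] += rec.n_pairs
    if multi:
        logger.info("%d DN types target multiple VNC groups and are counted in each", multi)
    return out


def write_connectivity(C: ConnectivityMatrix, path: str | Path) -> None:
    """Headed CSV (rows = VNC, columns = brain) plus JSON metadata sidecar."""
    path = Path(path)
    C.values.to_csv(path)
    meta = {
        "weighting": C.weighting,
        "brain_filter": C.brain_filter,
        "vnc_filter": C.vnc_filter,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))
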
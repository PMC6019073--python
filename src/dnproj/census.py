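"""Census statistics: half-up percentages, laterality, coverage, and tallies.

These reproduce the descriptive arithmetic of a DN survey: what fraction of
the estimated population was identified per soma cluster, the ipsilateral /
contralateral split of descending axons, and the breakdown into unique
types (single identifiable bilateral pairs) versus population types (small
groups of near-identical cells).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .catalog import DNCatalog, SOMA_GROUPS

logger = logging.getLogger(__name__)

__all__ = [
    "CensusTable",
    "LateralitySummary",
    "SummaryReport",
    "percent_round",
    "laterality_summary",
    "coverage_vs_census",
    "population_summary",
    "CLUSTER_SOMA_GROUPS",
]

#: Soma clusters used for coverage against a photoactivation census.
#: Group x (soma outside the brain) is excluded: the brain-surface census
#: cannot include it.
CLUSTER_SOMA_GROUPS: dict[str, tuple[str, ...]] = {
    "anterior": ("a", "b", "c", "d"),
    "posterior": ("p",),
    "gng": ("g",),
}


def percent_round(numerator: int, denominator: int, decimals: int = 0) -> float:
    """100*n/d rounded half-up (not banker's) to ``decimals`` places."""
    if denominator <= 0:
        raise ZeroDivisionError("denominator must be positive")
    pct = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    q = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CensusTable:
    """Photoactivation census counts of DN somata per cluster."""

    counts: dict[str, int]  # cluster -> censused cell count

    def __post_init__(self) -> None:
        for cluster, n in self.counts.items():
            if cluster not in CLUSTER_SOMA_GROUPS:
                raise ValueError(f"unknown soma cluster {cluster!r}")
            if not (isinstance(n, int) and n >= 0):
                raise ValueError(f"census count for {cluster!r} must be >= 0")


@dataclass
class LateralitySummary:
    ipsilateral: int
    contralateral: int
    unknown: int
    percent_ipsilateral: float
    level: str


def laterality_summary(catalog: DNCatalog, level: str = "cells") -> LateralitySummary:
    """Ipsi/contra tallies at type or cell level (cells weight by n_pairs).

    Records with unknown laterality are excluded from the percentage and
    reported separately.
    """
    if level not in ("types", "cells"):
        raise ValueError(f"unknown level {level!r}")
    tallies = {"ipsilateral": 0, "contralateral": 0, "unknown": 0}
    for rec in catalog.records:
        w = rec.n_pairs if level == "cells" else 1
        tallies[rec.laterality] += w
    if tallies["unknown"]:
        logger.warning(
            "%d %s with unknown laterality excluded from the percentage",
            tallies["unknown"],
            level,
        )
    known = tallies["ipsilateral"] + tallies["contralateral"]
    pct = percent_round(tallies["ipsilateral"], known, 0) if known else float("nan")
    return LateralitySummary(
        ipsilateral=tallies["ipsilateral"],
        contralateral=tallies["contralateral"],
        unknown=tallies["unknown"],
        percent_ipsilateral=pct,
        level=level,
    )


def coverage_vs_census(catalog: DNCatalog, census: CensusTable) -> dict[str, float]:
    """Identified-cell coverage per soma cluster, as whole percentages.

    Identified counts are pair-weighted sums over the catalog (anterior =
    soma groups a/b/c/d, posterior = p, gng = g; x excluded) divided by the
    censused cell count for the cluster.
    """
    identified = {c: 0 for c in CLUSTER_SOMA_GROUPS}
    for rec in catalog.records:
        for cluster, groups in CLUSTER_SOMA_GROUPS.items():
            if rec.soma_group in groups:
                identified[cluster] += rec.n_pairs
    out = {}
    for cluster in CLUSTER_SOMA_GROUPS:
        if cluster not in census.counts:
            raise KeyError(f"census is missing cluster {cluster!r}")
        out[cluster] = percent_round(identified[cluster], census.counts[cluster], 0)
    return out


@dataclass
class SummaryReport:
    """Catalog-wide census: totals, unique/population split, per-group tallies."""

    n_types: int
    n_pairs: int
    n_unique_types: int
    n_population_types: int
    n_population_cells: int
    per_soma_group_types: dict[str, int] = field(default_factory=dict)
    per_soma_group_pairs: dict[str, int] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_types": self.n_types,
            "n_pairs": self.n_pairs,
            "n_unique_types": self.n_unique_types,
            "n_population_types": self.n_population_types,
            "n_population_cells": self.n_population_cells,
            "per_soma_group_types": self.per_soma_group_types,
            "per_soma_group_pairs": self.per_soma_group_pairs,
        }


def population_summary(catalog: DNCatalog) -> SummaryReport:
    """Tally types and bilateral pairs, split by unique/population and soma group."""
    n_unique = sum(1 for r in catalog.records if r.kind == "unique")
    pop = [r for r in catalog.records if r.kind == "population"]
    per_types = {g: 0 for g in SOMA_GROUPS}
    per_pairs = {g: 0 for g in SOMA_GROUPS}
    for r in catalog.records:
        per_types[r.soma_group] += 1
        per_pairs[r.soma_group] += r.n_pairs
    return SummaryReport(
        n_types=len(catalog.records),
        n_pairs=sum(r.n_pairs for r in catalog.records),
        n_unique_types=n_unique,
        n_population_types=len(pop),
        n_population_cells=sum(r.n_pairs for r in pop),
        per_soma_group_types={g: n for g, n in per_types.items() if n},
        per_soma_group_pairs={g: n for g, n in per_pairs.items() if n},
    )
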
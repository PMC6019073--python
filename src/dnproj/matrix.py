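"""Binary innervation matrices and per-neuropil counts.

The central object is the DN-type x neuropil 0/1 matrix built from a catalog
under a polarity filter: ``smooth`` selects putative inputs (smooth or
both), ``varicose`` putative outputs (varicose or both), ``any`` selects any
innervation.  Counts can weight each row either as one type or by its number
of bilateral pairs ("cells" weighting).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import DNCatalog, NeuropilAtlas, Polarity

__all__ = [
    "InnervationMatrix",
    "BreadthSummary",
    "build_matrix",
    "neuropil_counts",
    "innervation_breadth",
    "select_types",
    "write_matrix",
    "read_matrix",
]

POLARITY_FILTERS = ("smooth", "varicose", "any")


def _matches(pol: Polarity, polarity_filter: str, intensity_threshold: int) -> bool:
    if polarity_filter == "smooth":
        ok = pol.value in ("smooth", "both")
    elif polarity_filter == "varicose":
        ok = pol.value in ("varicose", "both")
    elif polarity_filter == "any":
        ok = pol.value != "none"
    else:
        raise ValueError(f"unknown polarity filter {polarity_filter!r}")
    return ok and pol.effective_intensity() >= intensity_threshold


@dataclass
class InnervationMatrix:
    """Binary DN-type x neuropil matrix under a stated polarity filter."""

    rows: list[str]
    cols: list[str]
    values: np.ndarray  # shape (len(rows), len(cols)), dtype int8, 0/1
    polarity_filter: str
    side: str
    intensity_threshold: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.rows), len(self.cols)):
            raise ValueError("matrix shape does not match row/col labels")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("innervation matrix entries must be 0 or 1")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.rows, columns=self.cols)

    def row(self, type_id: str) -> np.ndarray:
        return self.values[self.rows.index(type_id)]

    def col(self, neuropil: str) -> np.ndarray:
        return self.values[:, self.cols.index(neuropil)]


def build_matrix(
    catalog: DNCatalog,
    atlas: NeuropilAtlas | None = None,
    polarity_filter: str = "any",
    intensity_threshold: int = 1,
    side: str | None = None,
) -> InnervationMatrix:
    """Build the binary innervation matrix for one side of the CNS.

    Entry (i, j) is 1 iff record i's polarity at neuropil j matches
    ``polarity_filter`` and its ordinal intensity (if annotated) is at least
    ``intensity_threshold`` (1 = sparse counts, 2 = dense only).
    """
    if polarity_filter not in POLARITY_FILTERS:
        raise ValueError(f"unknown polarity filter {polarity_filter!r}")
    if atlas is None:
        if side == "vnc":
            atlas = catalog.vnc_atlas
        else:
            atlas = catalog.brain_atlas
    if len(atlas) == 0:
        raise ValueError("empty atlas")
    side = side or atlas.side
    side_key = "vnc" if side == "vnc" else "brain"
    cols = list(atlas.abbreviations)
    rows = [r.type_id for r in catalog.records]
    values = np.zeros((len(rows), len(cols)), dtype=np.int8)
    for i, rec in enumerate(catalog.records):
        for j, np_abbrev in enumerate(cols):
            pol = rec.polarity(side_key, np_abbrev)
            if _matches(pol, polarity_filter, intensity_threshold):
                values[i, j] = 1
    return InnervationMatrix(rows, cols, values, polarity_filter, side, intensity_threshold)


def neuropil_counts(
    matrix: InnervationMatrix,
    catalog: DNCatalog | None = None,
    weighting: str = "types",
) -> pd.Series:
    """Per-neuropil innervation counts.

    ``types`` counts each DN type once (column sums); ``cells`` weights each
    innervating type by its number of bilateral pairs, counting DN neurons
    individually.
    """
    if weighting == "types":
        w = np.ones(len(matrix.rows), dtype=int)
    elif weighting == "cells":
        if catalog is None:
            raise ValueError("cells weighting requires the catalog")
        w = np.array([catalog.get(t).n_pairs for t in matrix.rows], dtype=int)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    counts = w @ matrix.values if len(matrix.rows) else np.zeros(len(matrix.cols), int)
    return pd.Series(np.asarray(counts, dtype=int), index=matrix.cols, name=weighting)


@dataclass
class BreadthSummary:
    """Per-type innervation breadth: how many neuropils each DN type reaches."""

    per_type: pd.Series
    mean: float
    sd: float  # population SD (ddof=0)
    histogram: pd.Series = field(repr=False)


def innervation_breadth(matrix: InnervationMatrix) -> BreadthSummary:
    """Row sums with mean, population SD, and a breadth histogram."""
    if len(matrix.rows) == 0:
        raise ValueError("empty matrix")
    sums = matrix.values.sum(axis=1)
    per_type = pd.Series(sums, index=matrix.rows, name="breadth")
    hist = per_type.value_counts().sort_index()
    hist = hist.reindex(range(0, int(sums.max()) + 1 if len(sums) else 1), fill_value=0)
    return BreadthSummary(
        per_type=per_type,
        mean=float(np.mean(sums)),
        sd=float(np.std(sums)),  # population SD
        histogram=hist,
    )


def select_types(matrix: InnervationMatrix, must_include: list[set[str] | list[str]]) -> list[str]:
    """Type ids innervating at least one neuropil from every given set.

    E.g. ``[{"wing"}, {"foreleg", "middle_leg", "hindleg"}]`` selects types
    with projections to both wing and leg neuropil.
    """
    for group in must_include:
        for np_abbrev in group:
            if np_abbrev not in matrix.cols:
                raise KeyError(f"unknown neuropil {np_abbrev!r}")
    out = []
    for i, tid in enumerate(matrix.rows):
        hit = matrix.values[i]
        if all(
            any(hit[matrix.cols.index(a)] for a in group) for group in must_include
        ):
            out.append(tid)
    return out


def write_matrix(matrix: InnervationMatrix, path: str | Path) -> None:
    """Write the matrix as headed CSV plus a JSON sidecar with filter metadata."""
    path = Path(path)
    matrix.to_dataframe().to_csv(path)
    meta = {
        "polarity_filter": matrix.polarity_filter,
        "side": matrix.side,
        "intensity_threshold": matrix.intensity_threshold,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_matrix(path: str | Path) -> InnervationMatrix:
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return InnervationMatrix(
        rows=list(df.index),
        cols=list(df.columns),
        values=df.to_numpy(),
        **meta,
    )
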
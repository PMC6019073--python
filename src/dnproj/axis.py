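"""Neurite density profiles along an anatomical axis.

A segmented neuron volume (integer label mask with per-axis voxel size) is
reduced to a 1-D voxel-count profile along one axis — conventionally
anterior-posterior at 1 µm bins — counting only neurite-labeled voxels and
excluding somata and axons.  Profiles can be max-normalized for display,
summarized by their center of mass (COM), ordered anterior-to-posterior,
and compared between projection classes with an exact-permutation rank-sum
test.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "VoxelMask",
    "AxisProfile",
    "RankSumResult",
    "profile_along_axis",
    "normalize_profile",
    "center_of_mass",
    "order_profiles",
    "com_class_association",
    "read_mask_tiff",
]

DEFAULT_SEMANTICS = {0: "background", 1: "neurite", 2: "soma", 3: "axon"}


@dataclass
class VoxelMask:
    """3-D integer label volume with voxel sizes (µm) and axis roles.

    ``axis_roles`` names the anatomical direction of each array axis, e.g.
    ``("AP", "DV", "ML")``.  ``semantics`` maps label integers to meanings
    (neurite / soma / axon / background).
    """

    labels: np.ndarray
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0)
    axis_roles: tuple[str, str, str] = ("AP", "DV", "ML")
    semantics: dict[int, str] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("mask must be a 3-D label array")
        if (self.labels < 0).any():
            raise ValueError("labels must be nonnegative")
        if self.semantics is None:
            self.semantics = dict(DEFAULT_SEMANTICS)

    def axis_index(self, axis: str | int) -> int:
        if isinstance(axis, int):
            return axis
        try:
            return self.axis_roles.index(axis)
        except ValueError:
            raise KeyError(f"no axis {axis!r}; roles are {self.axis_roles}") from None

    def labels_for(self, meanings: set[str]) -> set[int]:
        return {lab for lab, m in self.semantics.items() if m in meanings}


@dataclass
class AxisProfile:
    """Voxel counts per bin along an anatomical axis."""

    bin_starts_um: np.ndarray
    counts: np.ndarray
    bin_um: float = 1.0
    normalized: bool = False
    neuron_id: str = ""

    def __post_init__(self) -> None:
        self.bin_starts_um = np.asarray(self.bin_starts_um, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.bin_starts_um.shape != self.counts.shape:
            raise ValueError("bin positions and counts must align")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def total_mass(self) -> float:
        return float(self.counts.sum())


def profile_along_axis(
    mask: VoxelMask,
    axis: str | int = "AP",
    bin_um: float = 1.0,
    exclude: tuple[str, ...] = ("soma", "axon"),
    neuron_id: str = "",
) -> AxisProfile:
    """Count neurite voxels per ``bin_um`` bin along one axis.

    Bins are half-open intervals [k*bin, (k+1)*bin) µm from the volume
    origin.  Voxels whose label means one of ``exclude`` (default: somata
    and axons) are not counted.  An all-zero result (e.g. soma-only mask)
    is returned with a warning rather than an error.
    """
    if bin_um <= 0:
        raise ValueError("bin width must be positive")
    ax = mask.axis_index(axis)
    include = mask.labels_for({"neurite"})
    sel = np.isin(mask.labels, sorted(include))
    voxel = mask.voxel_size_um[ax]
    n_bins = max(1, math.ceil(mask.labels.shape[ax] * voxel / bin_um))
    counts = np.zeros(n_bins)
    idx = np.nonzero(sel)[ax]
    if idx.size == 0:
        logger.warning("no neurite voxels after exclusion; profile is all-zero")
    else:
        bins = np.floor(idx * voxel / bin_um).astype(int)
        np.add.at(counts, bins, 1)
    starts = np.arange(n_bins) * bin_um
    return AxisProfile(starts, counts, bin_um=bin_um, neuron_id=neuron_id)


def normalize_profile(p: AxisProfile) -> AxisProfile:
    """Divide by the maximum bin so the peak is 1; all-zero profiles pass through."""
    m = p.counts.max() if p.counts.size else 0.0
    if m == 0:
        logger.warning("zero-mass profile left unnormalized")
        return replace(p, normalized=True)
    return replace(p, counts=p.counts / m, normalized=True)


def center_of_mass(p: AxisProfile) -> float:
    """Count-weighted mean bin position (µm) of the profile."""
    total = p.counts.sum()
    if total <= 0:
        raise ValueError("center of mass undefined for a zero-mass profile")
    return float((p.bin_starts_um * p.counts).sum() / total)


def order_profiles(profiles: list[AxisProfile]) -> list[int]:
    """Indices that sort profiles by ascending center of mass (stable)."""
    coms = [center_of_mass(p) for p in profiles]
    return sorted(range(len(profiles)), key=lambda i: coms[i])


@dataclass
class RankSumResult:
    """Two-class rank-sum comparison of center-of-mass distributions."""

    statistic: float  # rank sum of the first class
    expected: float  # null expectation of the statistic
    more_posterior: str  # class label with the larger mean rank
    p_value: float
    method: str  # "exact" or "monte-carlo"


def com_class_association(
    profiles: list[AxisProfile],
    class_labels: list[str],
    max_exact: int = 20000,
    seed: int | None = 0,
) -> RankSumResult:
    """Wilcoxon rank-sum test of COM between two projection classes.

    Compares the center-of-mass distributions of the two classes (e.g.
    dorsal- vs leg-projecting DNs).  The two-sided p-value comes from the
    exact permutation distribution when the number of label assignments is
    at most ``max_exact``, otherwise from seeded Monte-Carlo sampling.
    """
    if len(profiles) != len(class_labels):
        raise ValueError("one class label per profile required")
    classes = sorted(set(class_labels))
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {classes}")
    a, b = classes
    coms = np.array([center_of_mass(p) for p in profiles])
    is_a = np.array([c == a for c in class_labels])
    n, n1 = len(coms), int(is_a.sum())
    if n1 == 0 or n1 == n:
        raise ValueError("both classes must be represented")
    ranks = rankdata(coms)
    W = float(ranks[is_a].sum())
    expected = n1 * (n + 1) / 2.0
    mean_a = coms[is_a].mean()
    mean_b = coms[~is_a].mean()
    more_posterior = a if mean_a > mean_b else b

    n_comb = math.comb(n, n1)
    if n_comb <= max_exact:
        null = np.array(
            [sum(ranks[list(c)]) for c in itertools.combinations(range(n), n1)]
        )
        p = float(np.mean(np.abs(null - expected) >= abs(W - expected) - 1e-12))
        method = "exact"
    else:
        rng = np.random.default_rng(seed)
        draws = np.array(
            [ranks[rng.permutation(n)[:n1]].sum() for _ in range(10000)]
        )
        p = float(
            (1 + np.sum(np.abs(draws - expected) >= abs(W - expected) - 1e-12))
            / (1 + draws.size)
        )
        method = "monte-carlo"
    return RankSumResult(W, expected, more_posterior, p, method)


def read_mask_tiff(
    path,
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0),
    axis_roles: tuple[str, str, str] = ("AP", "DV", "ML"),
    semantics: dict[int, str] | None = None,
) -> VoxelMask:
    """Load a labeled volume from a (multi-page) TIFF stack."""
    import tifffile

    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None, ...]
    return VoxelMask(arr.astype(np.int64), voxel_size_um, axis_roles, semantics)
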
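"""3D gray-level co-occurrence matrices over the 13 canonical first-ring directions.

A voxel in a 3D grid has 26 first-ring neighbours, giving 26 displacement
vectors.  Because the co-occurrence matrix of a vector is the transpose of the
matrix of its negated vector, only 13 canonical directions are kept.  They
split into three geometric scale groups by Euclidean sampling distance:

* G1 - the 3 axis directions (distance 1),
* G2 - the 6 in-plane diagonals (distance sqrt(2)),
* G3 - the 4 space diagonals (distance sqrt(3)).

This multi-scale partition is what the group-wise feature machinery downstream
builds on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product

import numpy as np

__all__ = [
    "Displacement",
    "QuantizedROI",
    "GLCM",
    "GLCMSet",
    "canonical_directions",
    "group_directions",
    "quantize_roi",
    "compute_glcm",
    "compute_glcm_set",
    "DEFAULT_N_LEVELS",
    "DEFAULT_CLEANSE_THRESHOLD",
]

DEFAULT_N_LEVELS = 32
#: HU threshold below which voxels are considered colonic air and discarded.
DEFAULT_CLEANSE_THRESHOLD = -450.0


@dataclass(frozen=True, order=True)
class Displacement:
    """A canonical first-ring displacement vector.

    Components lie in {-1, 0, 1}, not all zero, and the first nonzero
    component is positive so that ``v`` and ``-v`` are never both canonical.
    """

    offset: tuple[int, int, int]

    def __post_init__(self) -> None:
        off = tuple(int(c) for c in self.offset)
        if len(off) != 3 or any(c not in (-1, 0, 1) for c in off):
            raise ValueError(f"offset components must be in {{-1,0,1}}: {off}")
        if off == (0, 0, 0):
            raise ValueError("zero displacement is not a direction")
        nz = next(c for c in off if c != 0)
        if nz < 0:
            raise ValueError(
                f"non-canonical displacement {off}: first nonzero component must be positive"
            )
        object.__setattr__(self, "offset", off)

    @property
    def scale(self) -> float:
        """Euclidean sampling distance (1, sqrt(2) or sqrt(3))."""
        return math.sqrt(sum(c * c for c in self.offset))

    @property
    def group(self) -> int:
        """Scale group id: 1, 2 or 3 (squared norm)."""
        return sum(c * c for c in self.offset)

    @property
    def label(self) -> str:
        """Compact key like ``d_10-1`` used in archives and feature labels."""
        return "d_" + "".join(str(c) for c in self.offset)

    def negated(self) -> tuple[int, int, int]:
        return tuple(-c for c in self.offset)


def canonical_directions() -> list[Displacement]:
    """The 13 canonical first-ring directions, G1 then G2 then G3.

    Obtained from the 26 nonzero offsets in {-1,0,1}^3 by keeping one
    representative of each {v, -v} pair (first nonzero component positive),
    ordered by scale group and lexicographically within each group.
    """
    keep = []
    for off in product((-1, 0, 1), repeat=3):
        if off == (0, 0, 0):
            continue
        nz = next(c for c in off if c != 0)
        if nz > 0:
            keep.append(off)
    keep.sort(key=lambda o: (sum(c * c for c in o), o))
    return [Displacement(o) for o in keep]


def group_directions(
    dirs: list[Displacement],
) -> dict[int, list[Displacement]]:
    """Partition canonical directions into scale groups {1: G1, 2: G2, 3: G3}."""
    groups: dict[int, list[Displacement]] = {1: [], 2: [], 3: []}
    for d in dirs:
        g = d.group
        if g not in groups:
            raise ValueError(f"{d.offset} is not a first-ring displacement")
        groups[g].append(d)
    return groups


@dataclass
class QuantizedROI:
    """A cleansed, gray-level-quantized region of interest.

    ``levels`` holds integer gray levels in [0, n_levels-1]; ``mask`` marks
    voxels that survived cleansing and belong to the lesion.  ``provenance``
    records the cleanse threshold and the intensity bounds used for binning so
    a run can be reproduced exactly.
    """

    levels: np.ndarray
    mask: np.ndarray
    n_levels: int = DEFAULT_N_LEVELS
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.levels.shape != self.mask.shape:
            raise ValueError(
                f"levels shape {self.levels.shape} != mask shape {self.mask.shape}"
            )
        if self.mask.any():
            inside = self.levels[self.mask]
            if inside.min() < 0 or inside.max() >= self.n_levels:
                raise ValueError("in-mask levels outside [0, n_levels-1]")


def quantize_roi(
    volume: np.ndarray,
    mask: np.ndarray,
    n_levels: int = DEFAULT_N_LEVELS,
    cleanse_threshold: float = DEFAULT_CLEANSE_THRESHOLD,
) -> QuantizedROI:
    """Cleanse sub-threshold voxels and quantize the ROI to ``n_levels`` gray levels.

    Voxels with intensity below ``cleanse_threshold`` (air from the colonic
    lumen, in HU) are removed from the mask; they never contribute co-occurring
    pairs.  Surviving in-mask intensities are mapped to [0, n_levels-1] by
    equal-width binning between the post-cleanse in-mask minimum and maximum.
    A constant ROI maps to level 0 everywhere.

    Raises
    ------
    ValueError
        If the mask is empty after cleansing, shapes differ, or n_levels < 2.
    """
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if volume.shape != mask.shape:
        raise ValueError(f"volume shape {volume.shape} != mask shape {mask.shape}")
    if n_levels < 2:
        raise ValueError(f"n_levels must be >= 2, got {n_levels}")

    cleansed = mask & (volume >= cleanse_threshold)
    if not cleansed.any():
        raise ValueError(
            f"mask is empty after discarding voxels below {cleanse_threshold}"
        )

    inside = volume[cleansed]
    lo, hi = float(inside.min()), float(inside.max())
    levels = np.zeros(volume.shape, dtype=np.int64)
    if hi > lo:
        # floor(n * (v - lo) / (hi - lo)) with the top edge clipped into range
        scaled = np.floor((volume - lo) * (n_levels / (hi - lo)))
        levels = np.clip(scaled, 0, n_levels - 1).astype(np.int64)
    levels[~cleansed] = 0
    return QuantizedROI(
        levels=levels,
        mask=cleansed,
        n_levels=n_levels,
        provenance={
            "cleanse_threshold": cleanse_threshold,
            "intensity_min": lo,
            "intensity_max": hi,
            "degenerate_range": hi <= lo,
            "n_levels": n_levels,
        },
    )


@dataclass
class GLCM:
    """Co-occurrence counts for one displacement.

    ``counts[i, j]`` is the number of ordered in-mask voxel pairs
    ``(p, p + offset)`` whose gray levels are ``(i, j)``.  Pairs leaving the
    array or the mask are excluded.
    """

    counts: np.ndarray
    displacement: Displacement
    n_pairs: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if int(self.counts.sum()) != int(self.n_pairs):
            raise ValueError("counts do not sum to n_pairs")


@dataclass
class GLCMSet:
    """The 13 co-occurrence matrices of an ROI, partitioned by scale group."""

    glcms: dict[Displacement, GLCM]
    groups: dict[int, list[Displacement]]
    n_levels: int = DEFAULT_N_LEVELS

    def __post_init__(self) -> None:
        if len(self.glcms) != 13:
            raise ValueError(f"expected 13 matrices, got {len(self.glcms)}")
        sizes = tuple(len(self.groups[g]) for g in (1, 2, 3))
        if sizes != (3, 6, 4):
            raise ValueError(f"group sizes must be (3, 6, 4), got {sizes}")

    def ordered_directions(self) -> list[Displacement]:
        return [d for g in (1, 2, 3) for d in self.groups[g]]

    def stacked(self, dirs: list[Displacement] | None = None) -> np.ndarray:
        """Stack normalized matrices into an (n_levels, n_levels, c) array."""
        dirs = self.ordered_directions() if dirs is None else dirs
        mats = []
        for d in dirs:
            g = self.glcms[d]
            total = max(g.n_pairs, 1)
            mats.append(g.counts.astype(float) / total)
        return np.stack(mats, axis=-1)


def compute_glcm(roi: QuantizedROI, d: Displacement) -> GLCM:
    """Co-occurrence matrix of ``roi`` for displacement ``d`` (vectorized).

    Both endpoints of a pair must be in-mask; boundary-crossing pairs are
    dropped.  Equivalent to the per-pair double loop over the volume.
    """
    dz, dy, dx = d.offset
    shape = roi.levels.shape

    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for axis, off in enumerate((dz, dy, dx)):
        if off > 0:
            src[axis] = slice(0, shape[axis] - off)
            dst[axis] = slice(off, shape[axis])
        elif off < 0:
            src[axis] = slice(-off, shape[axis])
            dst[axis] = slice(0, shape[axis] + off)
    src_t, dst_t = tuple(src), tuple(dst)

    valid = roi.mask[src_t] & roi.mask[dst_t]
    i = roi.levels[src_t][valid]
    j = roi.levels[dst_t][valid]
    n = roi.n_levels
    counts = np.bincount(i * n + j, minlength=n * n).reshape(n, n)
    return GLCM(counts=counts, displacement=d, n_pairs=int(counts.sum()))


def compute_glcm_set(roi: QuantizedROI) -> GLCMSet:
    """All 13 canonical co-occurrence matrices of an ROI, grouped by scale."""
    dirs = canonical_directions()
    glcms = {d: compute_glcm(roi, d) for d in dirs}
    return GLCMSet(glcms=glcms, groups=group_directions(dirs), n_levels=roi.n_levels)
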
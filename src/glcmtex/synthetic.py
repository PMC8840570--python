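"""Synthetic lesion phantoms and feature tables with known ground truth.

The phantom generator emulates the statistical structure the texture pipeline
is sensitive to, not lesion anatomy: each sample is a correlated Gaussian
random field inside an irregular ellipsoidal mask, embedded in an HU-scaled
volume.  The two classes differ only in their spatial correlation structure
(an isotropic short correlation length versus an anisotropic long one); the
in-mask first-order intensity statistics are renormalized to identical mean
and spread, so any class signal must come from second-order (co-occurrence)
features.  A fraction of in-mask voxels is set to air-like values below the
cleanse threshold so the cleansing step is exercised end to end.

The table generator produces grouped feature matrices with a known set of
informative columns (a class-mean shift of ``delta`` standard deviations) for
isolated testing of the selection machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .glcm import DEFAULT_CLEANSE_THRESHOLD
from .selection import FeatureTable

__all__ = [
    "PhantomSpec",
    "TableSpec",
    "PhantomDataset",
    "make_phantoms",
    "make_feature_table",
]


@dataclass
class PhantomSpec:
    """Study conditions for the 3D phantom generator.

    Defaults mirror a small CT-colonography lesion cohort: 63 lesions split
    31 benign / 32 malignant, ~32 mm cubes at 1 mm voxels, soft-tissue
    intensities around 40 HU with a 100 HU spread, and ~5% residual air
    voxels below the -450 HU cleanse threshold.
    """

    n_benign: int = 31
    n_malignant: int = 32
    shape: tuple[int, int, int] = (32, 32, 32)
    corr_length_benign: float = 1.0  # isotropic correlation length (voxels)
    corr_length_malignant: float = 4.0  # along the anisotropy axis
    anisotropy_axis: int = 0
    intensity_mean: float = 40.0  # HU
    intensity_std: float = 100.0  # HU
    air_fraction: float = 0.05
    air_value: float = -1000.0  # HU, well below the cleanse threshold
    mask_radius_frac: float = 0.38  # ellipsoid radii as a fraction of shape
    mask_irregularity: float = 0.15  # relative boundary perturbation
    cleanse_threshold: float = DEFAULT_CLEANSE_THRESHOLD
    seed: int = 0


@dataclass
class PhantomDataset:
    volumes: list[np.ndarray]
    masks: list[np.ndarray]
    labels: np.ndarray
    ground_truth: dict = field(default_factory=dict)


def _irregular_ellipsoid(
    shape: tuple[int, int, int], radius_frac: float, irregularity: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Axis-aligned ellipsoid mask with a smooth random boundary perturbation."""
    center = [(s - 1) / 2.0 for s in shape]
    radii = [radius_frac * s * rng.uniform(0.85, 1.0) for s in shape]
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    r2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    bump = gaussian_filter(rng.standard_normal(shape), sigma=4.0)
    bump = bump / (np.abs(bump).max() + 1e-12)
    mask = r2 <= 1.0 + irregularity * bump
    if not mask.any():
        raise ValueError("degenerate phantom spec: empty mask")
    return mask


def _textured_field(
    shape: tuple[int, int, int], sigmas: tuple[float, float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Correlated Gaussian field: white noise smoothed at the given lengths."""
    return gaussian_filter(rng.standard_normal(shape), sigma=sigmas)


def make_phantoms(spec: PhantomSpec) -> PhantomDataset:
    """Generate the two-class phantom cohort.

    Class 0 (benign) uses isotropic smoothing at ``corr_length_benign``;
    class 1 (malignant) uses ``corr_length_malignant`` along the anisotropy
    axis and the benign length elsewhere.  After smoothing, the non-air
    in-mask voxels of every sample are standardized to exactly the target
    mean/STD, so first-order statistics carry no class signal.
    """
    if spec.n_benign < 1 or spec.n_malignant < 1:
        raise ValueError("need at least one sample per class")
    if spec.air_value >= spec.cleanse_threshold:
        raise ValueError("air_value must fall below the cleanse threshold")
    rng = np.random.default_rng(spec.seed)
    volumes, masks, labels = [], [], []
    sig_b = (spec.corr_length_benign,) * 3
    sig_m = [spec.corr_length_benign] * 3
    sig_m[spec.anisotropy_axis] = spec.corr_length_malignant
    for label, n, sig in ((0, spec.n_benign, sig_b), (1, spec.n_malignant, tuple(sig_m))):
        for _ in range(n):
            mask = _irregular_ellipsoid(
                spec.shape, spec.mask_radius_frac, spec.mask_irregularity, rng
            )
            field_ = _textured_field(spec.shape, sig, rng)
            vol = np.full(spec.shape, spec.air_value, dtype=float)
            inside = field_[mask]
            # exact first-order matching: standardize, then rescale
            std = inside.std()
            if std <= 0:
                raise ValueError("degenerate texture field (zero variance)")
            z = (field_ - inside.mean()) / std
            vol[mask] = spec.intensity_mean + spec.intensity_std * z[mask]
            # inject sub-threshold air voxels inside the mask
            n_air = int(round(spec.air_fraction * mask.sum()))
            if n_air > 0:
                flat = np.flatnonzero(mask)
                air_idx = rng.choice(flat, size=n_air, replace=False)
                vol.ravel()[air_idx] = spec.air_value
            volumes.append(vol)
            masks.append(mask)
            labels.append(label)
    return PhantomDataset(
        volumes=volumes,
        masks=masks,
        labels=np.asarray(labels),
        ground_truth={
            "corr_length_benign": spec.corr_length_benign,
            "corr_length_malignant": spec.corr_length_malignant,
            "anisotropy_axis": spec.anisotropy_axis,
            "null": spec.corr_length_benign == spec.corr_length_malignant,
        },
    )


@dataclass
class TableSpec:
    """Study conditions for grouped feature tables with planted signal.

    ``group_sizes`` maps group id to column count; ``informative_per_group``
    gives how many leading columns of each group carry a class-mean shift of
    ``delta`` pooled standard deviations.  All other columns are standard
    normal noise independent of the label.
    """

    n_benign: int = 31
    n_malignant: int = 32
    group_sizes: dict[int, int] = field(default_factory=lambda: {1: 20, 2: 20, 3: 15})
    informative_per_group: dict[int, int] = field(
        default_factory=lambda: {1: 2, 2: 2, 3: 1}
    )
    delta: float = 1.0
    seed: int = 0


def make_feature_table(spec: TableSpec) -> tuple[FeatureTable, dict]:
    """Generate a grouped feature table and its ground truth.

    Returns the table and a dict with the informative column indices.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_benign + spec.n_malignant
    y = np.concatenate([np.zeros(spec.n_benign, int), np.ones(spec.n_malignant, int)])
    cols, names, groups, informative = [], [], [], []
    pos = 0
    for g in sorted(spec.group_sizes):
        size = spec.group_sizes[g]
        k = spec.informative_per_group.get(g, 0)
        if k > size:
            raise ValueError(f"group {g}: more informative features than columns")
        for j in range(size):
            x = rng.standard_normal(n)
            if j < k:
                x = x + spec.delta * y
                informative.append(pos)
            cols.append(x)
            names.append(f"g{g}_f{j}")
            groups.append(g)
            pos += 1
    table = FeatureTable(
        matrix=np.column_stack(cols),
        labels=y,
        feature_labels=names,
        group_assignment=np.asarray(groups),
    )
    return table, {"informative_idx": np.asarray(informative), "delta": spec.delta}
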
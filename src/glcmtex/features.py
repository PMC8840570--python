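"""Texture measures over co-occurrence matrices and the multi-scale descriptor.

The default registry holds 28 per-matrix statistical measures: Haralick's
canonical 14 plus 14 standard co-occurrence extensions (autocorrelation,
cluster statistics, the inverse-difference family, and energies/entropies of
the marginal, sum and difference distributions).  Applied to the 13 canonical
directions this yields the 364-variable descriptor, splittable into the three
scale-group sub-descriptors of length 84 (G1), 168 (G2) and 112 (G3).

The registry is an ordered, pluggable list: any measure set can be dropped in
and every structural size downstream (|registry| x 13, per-group slices,
2 x |registry| direction-pooled baselines) follows from its length.

Conventions: natural logarithms; 0*log(0) = 0; correlation-type measures are
defined as 0 when a marginal variance vanishes (constant ROI), so every
measure is finite on every valid normalized matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .glcm import GLCM, GLCMSet, Displacement

__all__ = [
    "MeasureRegistry",
    "Descriptor",
    "BaselineFeatures",
    "normalize_glcm",
    "apply_measures",
    "build_descriptor",
    "split_descriptor",
    "baseline_features",
    "default_registry",
    "haralick14_registry",
]


class GLCMStats:
    """Shared per-matrix statistics, computed once and handed to every measure."""

    def __init__(self, p: np.ndarray):
        n = p.shape[0]
        self.p = p
        self.n = n
        self.idx = np.arange(n, dtype=float)
        self.px = p.sum(axis=1)
        self.py = p.sum(axis=0)
        self.mu_x = float(self.idx @ self.px)
        self.mu_y = float(self.idx @ self.py)
        self.var_x = float(((self.idx - self.mu_x) ** 2) @ self.px)
        self.var_y = float(((self.idx - self.mu_y) ** 2) @ self.py)
        ii, jj = np.meshgrid(self.idx, self.idx, indexing="ij")
        self.ii, self.jj = ii, jj
        # distribution of i+j over 0..2n-2 and of |i-j| over 0..n-1
        self.p_sum = np.bincount(
            (ii + jj).astype(int).ravel(), weights=p.ravel(), minlength=2 * n - 1
        )
        self.p_diff = np.bincount(
            np.abs(ii - jj).astype(int).ravel(), weights=p.ravel(), minlength=n
        )


def _xlogx(v: np.ndarray) -> np.ndarray:
    out = np.zeros_like(v)
    pos = v > 0
    out[pos] = v[pos] * np.log(v[pos])
    return out


def _entropy(v: np.ndarray) -> float:
    return float(-_xlogx(v).sum())


# --- Haralick's canonical 14 ------------------------------------------------

def _asm(s: GLCMStats) -> float:
    return float((s.p ** 2).sum())


def _contrast(s: GLCMStats) -> float:
    k = np.arange(s.n, dtype=float)
    return float((k ** 2) @ s.p_diff)


def _correlation(s: GLCMStats) -> float:
    denom = np.sqrt(s.var_x * s.var_y)
    if denom <= 0:
        return 0.0
    return float(((s.ii * s.jj * s.p).sum() - s.mu_x * s.mu_y) / denom)


def _variance(s: GLCMStats) -> float:
    # sum-of-squares variance about the row-marginal mean
    return float((((s.ii - s.mu_x) ** 2) * s.p).sum())


def _idm(s: GLCMStats) -> float:
    return float((s.p / (1.0 + (s.ii - s.jj) ** 2)).sum())


def _sum_average(s: GLCMStats) -> float:
    k = np.arange(2 * s.n - 1, dtype=float)
    return float(k @ s.p_sum)


def _sum_variance(s: GLCMStats) -> float:
    k = np.arange(2 * s.n - 1, dtype=float)
    mu = k @ s.p_sum
    return float(((k - mu) ** 2) @ s.p_sum)


def _sum_entropy(s: GLCMStats) -> float:
    return _entropy(s.p_sum)


def _joint_entropy(s: GLCMStats) -> float:
    return _entropy(s.p)


def _difference_variance(s: GLCMStats) -> float:
    k = np.arange(s.n, dtype=float)
    mu = k @ s.p_diff
    return float(((k - mu) ** 2) @ s.p_diff)


def _difference_entropy(s: GLCMStats) -> float:
    return _entropy(s.p_diff)


def _imc1(s: GLCMStats) -> float:
    hxy = _entropy(s.p)
    hx, hy = _entropy(s.px), _entropy(s.py)
    outer = np.outer(s.px, s.py)
    log_outer = np.zeros_like(outer)
    np.log(outer, out=log_outer, where=outer > 0)
    hxy1 = float(-(s.p * log_outer).sum())
    denom = max(hx, hy)
    if denom <= 0:
        return 0.0
    return float((hxy - hxy1) / denom)


def _imc2(s: GLCMStats) -> float:
    hxy = _entropy(s.p)
    outer = np.outer(s.px, s.py)
    hxy2 = float(-_xlogx(outer).sum())
    arg = 1.0 - np.exp(-2.0 * (hxy2 - hxy))
    return float(np.sqrt(max(arg, 0.0)))


def _mcc(s: GLCMStats) -> float:
    # second-largest eigenvalue of Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) py(k))
    keep_r = s.px > 0
    keep_c = s.py > 0
    p = s.p[np.ix_(keep_r, keep_c)]
    px = s.px[keep_r]
    py = s.py[keep_c]
    if p.shape[0] < 2 or p.shape[1] < 2:
        return 0.0
    q = (p / px[:, None]) @ (p / py[None, :]).T
    ev = np.sort(np.abs(np.linalg.eigvals(q)))
    second = float(ev[-2].real) if ev.size >= 2 else 0.0
    return float(np.sqrt(max(second, 0.0)))


# --- 14 standard extensions -------------------------------------------------

def _autocorrelation(s: GLCMStats) -> float:
    return float((s.ii * s.jj * s.p).sum())


def _joint_average(s: GLCMStats) -> float:
    return s.mu_x


def _cluster_moment(s: GLCMStats, power: int) -> float:
    dev = s.ii + s.jj - s.mu_x - s.mu_y
    return float(((dev ** power) * s.p).sum())


def _dissimilarity(s: GLCMStats) -> float:
    k = np.arange(s.n, dtype=float)
    return float(k @ s.p_diff)


def _max_probability(s: GLCMStats) -> float:
    return float(s.p.max())


def _inverse_difference(s: GLCMStats) -> float:
    return float((s.p / (1.0 + np.abs(s.ii - s.jj))).sum())


def _idn(s: GLCMStats) -> float:
    return float((s.p / (1.0 + np.abs(s.ii - s.jj) / s.n)).sum())


def _idmn(s: GLCMStats) -> float:
    return float((s.p / (1.0 + (s.ii - s.jj) ** 2 / s.n ** 2)).sum())


def _inverse_variance(s: GLCMStats) -> float:
    off = s.ii != s.jj
    d2 = (s.ii - s.jj) ** 2
    return float((s.p[off] / d2[off]).sum())


def _marginal_entropy(s: GLCMStats) -> float:
    return _entropy(s.px)


def _difference_energy(s: GLCMStats) -> float:
    return float((s.p_diff ** 2).sum())


def _sum_energy(s: GLCMStats) -> float:
    return float((s.p_sum ** 2).sum())


_HARALICK14: list[tuple[str, Callable[[GLCMStats], float]]] = [
    ("angular_second_moment", _asm),
    ("contrast", _contrast),
    ("correlation", _correlation),
    ("variance", _variance),
    ("inverse_difference_moment", _idm),
    ("sum_average", _sum_average),
    ("sum_variance", _sum_variance),
    ("sum_entropy", _sum_entropy),
    ("entropy", _joint_entropy),
    ("difference_variance", _difference_variance),
    ("difference_entropy", _difference_entropy),
    ("information_correlation_1", _imc1),
    ("information_correlation_2", _imc2),
    ("maximal_correlation_coefficient", _mcc),
]

_EXTENSIONS14: list[tuple[str, Callable[[GLCMStats], float]]] = [
    ("autocorrelation", _autocorrelation),
    ("joint_average", _joint_average),
    ("cluster_tendency", lambda s: _cluster_moment(s, 2)),
    ("cluster_shade", lambda s: _cluster_moment(s, 3)),
    ("cluster_prominence", lambda s: _cluster_moment(s, 4)),
    ("dissimilarity", _dissimilarity),
    ("maximum_probability", _max_probability),
    ("inverse_difference", _inverse_difference),
    ("inverse_difference_normalized", _idn),
    ("inverse_difference_moment_normalized", _idmn),
    ("inverse_variance", _inverse_variance),
    ("marginal_entropy", _marginal_entropy),
    ("difference_energy", _difference_energy),
    ("sum_energy", _sum_energy),
]


@dataclass
class MeasureRegistry:
    """Ordered, named list of per-matrix measures; order fixes descriptor columns."""

    measures: list[tuple[str, Callable[[GLCMStats], float]]]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.measures]
        if len(set(names)) != len(names):
            raise ValueError("measure names must be unique")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.measures]

    def __len__(self) -> int:
        return len(self.measures)


def default_registry() -> MeasureRegistry:
    """The 28-measure set: Haralick's 14 plus 14 co-occurrence extensions."""
    return MeasureRegistry(measures=_HARALICK14 + _EXTENSIONS14)


def haralick14_registry() -> MeasureRegistry:
    """The classical 14 Haralick measures only."""
    return MeasureRegistry(measures=list(_HARALICK14))


def normalize_glcm(glcm: GLCM, symmetrize: bool = True) -> np.ndarray:
    """Turn counts into a probability matrix; optionally use (C + C^T) first.

    Symmetrizing is the classical Haralick convention: it makes the matrix
    direction-agnostic within a {v, -v} pair without changing any symmetric
    measure.
    """
    if glcm.n_pairs <= 0:
        raise ValueError(
            f"GLCM for displacement {glcm.displacement.offset} has zero pairs"
        )
    c = glcm.counts.astype(float)
    if symmetrize:
        c = c + c.T
    return c / c.sum()


def apply_measures(p: np.ndarray, registry: MeasureRegistry) -> np.ndarray:
    """Evaluate every registry measure on one normalized matrix, in order."""
    total = p.sum()
    if not np.isclose(total, 1.0, atol=1e-8):
        raise ValueError(f"matrix is not normalized (sum={total})")
    stats = GLCMStats(np.asarray(p, dtype=float))
    out = np.empty(len(registry))
    for k, (name, fn) in enumerate(registry.measures):
        v = fn(stats)
        if not np.isfinite(v):
            raise ValueError(f"measure {name!r} returned non-finite value {v}")
        out[k] = v
    return out


@dataclass
class Descriptor:
    """The measure-by-direction feature vector with its scale-group slices."""

    values: np.ndarray
    labels: list[tuple[str, Displacement]]
    group_slices: dict[int, slice]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.labels):
            raise ValueError("values and labels length mismatch")

    @property
    def feature_names(self) -> list[str]:
        return [f"{m}__{d.label}" for m, d in self.labels]


@dataclass
class BaselineFeatures:
    """Direction-pooled features: per-measure mean and range over 13 directions."""

    values: np.ndarray
    labels: list[str] = field(default_factory=list)


def build_descriptor(
    glcms: GLCMSet,
    registry: MeasureRegistry | None = None,
    symmetrize: bool = True,
) -> Descriptor:
    """The full multi-scale descriptor (364 values at the 28-measure default).

    Layout is direction-major: directions in canonical order (G1 then G2 then
    G3), registry order within each direction, so group slices are contiguous.
    """
    registry = default_registry() if registry is None else registry
    m = len(registry)
    values: list[np.ndarray] = []
    labels: list[tuple[str, Displacement]] = []
    group_slices: dict[int, slice] = {}
    pos = 0
    for g in (1, 2, 3):
        start = pos
        for d in glcms.groups[g]:
            p = normalize_glcm(glcms.glcms[d], symmetrize=symmetrize)
            values.append(apply_measures(p, registry))
            labels.extend((name, d) for name in registry.names)
            pos += m
        group_slices[g] = slice(start, pos)
    return Descriptor(
        values=np.concatenate(values), labels=labels, group_slices=group_slices
    )


def split_descriptor(d: Descriptor) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """The three scale-group sub-vectors (lengths 84/168/112 at defaults)."""
    return tuple(d.values[d.group_slices[g]] for g in (1, 2, 3))


def baseline_features(
    glcms: GLCMSet,
    registry: MeasureRegistry | None = None,
    symmetrize: bool = True,
) -> BaselineFeatures:
    """Traditional direction-pooled features: mean and range per measure.

    With the 28-measure registry this is the 56-value extended-Haralick
    baseline; restricted to the classical 14 measures it is the traditional
    28-value Haralick feature set.
    """
    registry = default_registry() if registry is None else registry
    per_dir = np.stack(
        [
            apply_measures(normalize_glcm(glcms.glcms[d], symmetrize=symmetrize), registry)
            for d in glcms.ordered_directions()
        ]
    )  # (13, |registry|)
    means = per_dir.mean(axis=0)
    ranges = per_dir.max(axis=0) - per_dir.min(axis=0)
    values = np.concatenate([means, ranges])
    labels = [f"{n}__mean" for n in registry.names] + [
        f"{n}__range" for n in registry.names
    ]
    return BaselineFeatures(values=values, labels=labels)
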
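"""Radiomic feature extraction: absolute discretization, gray-level matrices
and the 11 PET indices.

The feature set comprises five conventional (first-order) indices — SUVmean,
SUVmax, SUVpeak, MV (metabolic volume, mL) and TLG (total lesion glycolysis,
SUVmean x MV) — and six textural indices computed on SUV values discretized
over a fixed absolute range (default 128 levels over [0, 40] SUV):

* Homogeneity and Entropy from the gray-level co-occurrence matrix (GLCM),
* short- and long-run emphasis (SRE, LRE) from the run-length matrix (GLRLM),
* low- and high-gray-level zone emphasis (LGZE, HGZE) from the zone-length
  matrix (GLZLM).

GLCM and GLRLM are computed along the 13 independent directions linking a
voxel to its 26 neighbors and each feature is the unweighted mean over those
directions; GLZLM is direction-independent (26-connected zones in 3D).
Offsets live in index space: no physical-distance weighting is applied on
anisotropic grids.

Absolute (fixed-bound) discretization decouples texture values from the
metabolic volume, unlike per-lesion min-max rescaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal
from sklearn.base import BaseEstimator, TransformerMixin

from .segmentation import STRUCTURE_26, sphere_radius_mm
from .volumes import PETVolume, VOIMask

__all__ = [
    "FEATURE_NAMES",
    "TEXTURE_NAMES",
    "CONVENTIONAL_NAMES",
    "DiscretizationSpec",
    "DiscretizedVOI",
    "GrayLevelMatrix",
    "discretize",
    "direction_set",
    "glcm",
    "glrlm",
    "glzlm",
    "glcm_features",
    "glrlm_features",
    "glzlm_features",
    "texture_features",
    "conventional_features",
    "extract_all",
    "RadiomicsExtractor",
]

CONVENTIONAL_NAMES = ("SUVmean", "SUVmax", "SUVpeak", "MV", "TLG")
TEXTURE_NAMES = ("Homogeneity", "Entropy", "SRE", "LRE", "LGZE", "HGZE")
#: Canonical column order for feature tables.
FEATURE_NAMES = CONVENTIONAL_NAMES + TEXTURE_NAMES

#: Sentinel level for out-of-mask voxels.
_OUT = -1


@dataclass(frozen=True)
class DiscretizationSpec:
    """Absolute intensity discretization: ``n_bins`` levels over fixed SUV
    bounds shared by all patients (default 128 levels over [0, 40] SUV,
    i.e. a bin width of 40/128 ~ 0.3 SUV)."""

    n_bins: int = 128
    lower_bound: float = 0.0
    upper_bound: float = 40.0

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError(f"n_bins must be >= 2, got {self.n_bins}")
        if not self.upper_bound > self.lower_bound:
            raise ValueError("upper_bound must exceed lower_bound")

    @property
    def bin_width(self) -> float:
        return (self.upper_bound - self.lower_bound) / self.n_bins


@dataclass
class DiscretizedVOI:
    """Integer gray levels for the in-mask voxels of one VOI.

    ``levels`` is a full 3D array holding a level in ``[0, n_bins]`` inside
    the mask and the sentinel ``-1`` outside; out-of-mask voxels never enter
    any matrix.
    """

    levels: np.ndarray
    spec: DiscretizationSpec
    mask: VOIMask
    spacing: tuple[float, float, float]

    @property
    def n_levels(self) -> int:
        return self.spec.n_bins + 1


def discretize(vol: PETVolume, mask: VOIMask, spec: DiscretizationSpec | None = None) -> DiscretizedVOI:
    """Discretize in-mask SUV values onto the absolute scale of ``spec``.

    ``level(x) = round(n_bins * (x - lower) / (upper - lower))`` with
    round-half-away-from-zero; values above the upper bound clamp to
    ``n_bins``. Negative SUV (residual reconstruction noise) clamps to 0
    with a warning.
    """
    spec = spec or DiscretizationSpec()
    if mask.shape != vol.shape:
        raise ValueError("mask grid does not match the volume")
    if mask.n_voxels == 0:
        raise ValueError("mask is empty")
    x = vol.data[mask.data]
    if np.any(x < 0):
        warnings.warn("negative SUV values inside the mask clamped to 0", stacklevel=2)
        x = np.maximum(x, 0.0)
    scaled = spec.n_bins * (x - spec.lower_bound) / (spec.upper_bound - spec.lower_bound)
    # round half away from zero (values are >= 0 here)
    lev = np.floor(scaled + 0.5).astype(np.int64)
    lev = np.clip(lev, 0, spec.n_bins)
    levels = np.full(vol.shape, _OUT, dtype=np.int64)
    levels[mask.data] = lev
    return DiscretizedVOI(levels, spec, mask, vol.spacing)


def direction_set() -> list[tuple[int, int, int]]:
    """The 13 independent 3D directions between a voxel and its 26 neighbors.

    Sign-unique nonzero offsets of {-1, 0, 1}^3: each direction appears once
    (an offset and its negation describe the same direction).
    """
    dirs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                d = (dx, dy, dz)
                if d == (0, 0, 0):
                    continue
                if d > tuple(-c for c in d):
                    dirs.append(d)
    return dirs


@dataclass
class GrayLevelMatrix:
    """A gray-level counting matrix.

    ``counts[i, j]`` is indexed by gray level ``i`` and, depending on
    ``kind``: co-occurring level ``j`` (GLCM), run length ``j`` (GLRLM,
    column 0 unused) or zone size ``j`` (GLZLM, column 0 unused).
    """

    kind: str
    counts: np.ndarray
    direction: tuple[int, int, int] | None = None

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _pair_slices(offset):
    """Slicers (src, dst) with ``arr[dst]`` = voxels u, ``arr[src]`` = u - offset."""
    src, dst = [], []
    for o in offset:
        if o == 1:
            src.append(slice(0, -1))
            dst.append(slice(1, None))
        elif o == -1:
            src.append(slice(1, None))
            dst.append(slice(0, -1))
        elif o == 0:
            src.append(slice(None))
            dst.append(slice(None))
        else:
            raise ValueError(f"offset components must be in {{-1,0,1}}, got {offset}")
    return tuple(src), tuple(dst)


def glcm(d: DiscretizedVOI, offset: tuple[int, int, int]) -> GrayLevelMatrix:
    """Symmetric co-occurrence matrix for one distance-1 offset.

    Counts every ordered pair of in-mask voxels ``(v, v + offset)``; each
    unordered pair therefore contributes to both ``(i, j)`` and ``(j, i)``.
    """
    lv = d.levels
    n = d.n_levels
    src, dst = _pair_slices(offset)
    a = lv[src].ravel()
    b = lv[dst].ravel()
    ok = (a >= 0) & (b >= 0)
    c = np.bincount(a[ok] * n + b[ok], minlength=n * n).reshape(n, n)
    return GrayLevelMatrix("GLCM", c + c.T, tuple(offset))


def glrlm(d: DiscretizedVOI, offset: tuple[int, int, int]) -> GrayLevelMatrix:
    """Run-length matrix along one direction.

    ``counts[i, L]`` is the number of maximal runs of ``L`` consecutive
    in-mask voxels at level ``i`` along lines parallel to ``offset``; runs
    break at mask boundaries. A direction and its negation give identical
    runs.
    """
    offset = tuple(int(o) for o in offset)
    nz = [k for k in range(3) if offset[k] != 0]
    if not nz:
        raise ValueError("offset must be nonzero")
    ax = nz[0]
    if offset[ax] < 0:  # runs are orientation-free
        offset = tuple(-o for o in offset)
    lv = d.levels
    shape = lv.shape
    src, dst = _pair_slices(offset)

    same = np.zeros(shape, dtype=bool)
    same[dst] = (lv[dst] == lv[src]) & (lv[dst] >= 0) & (lv[src] >= 0)

    # run position counter: f[u] = f[u - offset] + 1 where the run continues
    f = (lv >= 0).astype(np.int64)
    u_sl = [slice(None)] * 3
    p_sl = [slice(None)] * 3
    for k in range(3):
        if k == ax:
            continue
        if offset[k] == 1:
            u_sl[k], p_sl[k] = slice(1, None), slice(0, -1)
        elif offset[k] == -1:
            u_sl[k], p_sl[k] = slice(0, -1), slice(1, None)
    for t in range(1, shape[ax]):
        u_sl[ax], p_sl[ax] = t, t - 1
        u, p = tuple(u_sl), tuple(p_sl)
        f[u] = np.where(same[u], f[p] + 1, f[u])

    # a voxel ends a run iff no successor continues it
    cont_next = np.zeros(shape, dtype=bool)
    cont_next[src] = same[dst]
    ends = (lv >= 0) & ~cont_next
    levels = lv[ends]
    lengths = f[ends]
    max_len = int(lengths.max()) if lengths.size else 1
    counts = np.zeros((d.n_levels, max_len + 1), dtype=np.int64)
    np.add.at(counts, (levels, lengths), 1)
    return GrayLevelMatrix("GLRLM", counts, offset)


def glzlm(d: DiscretizedVOI) -> GrayLevelMatrix:
    """Zone-length matrix: 26-connected same-level zones by level and size."""
    lv = d.levels
    inm = lv >= 0
    levels_present = np.unique(lv[inm])
    sizes_by_level: list[tuple[int, np.ndarray]] = []
    max_size = 1
    for level in levels_present:
        lab, n = ndimage.label(lv == level, structure=STRUCTURE_26)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        sizes_by_level.append((int(level), sizes))
        max_size = max(max_size, int(sizes.max()))
    counts = np.zeros((d.n_levels, max_size + 1), dtype=np.int64)
    for level, sizes in sizes_by_level:
        np.add.at(counts[level], sizes, 1)
    return GrayLevelMatrix("GLZLM", counts)


def _normalize(m: GrayLevelMatrix) -> np.ndarray | None:
    tot = m.counts.sum()
    if tot == 0:
        return None
    return m.counts / tot


def glcm_features(m: GrayLevelMatrix) -> dict[str, float] | None:
    """Homogeneity and Entropy of one co-occurrence matrix (None if empty)."""
    p = _normalize(m)
    if p is None:
        return None
    i, j = np.nonzero(p)
    pij = p[i, j]
    return {
        "Homogeneity": float(np.sum(pij / (1.0 + np.abs(i - j)))),
        "Entropy": float(-np.sum(pij * np.log2(pij))),
    }


def glrlm_features(m: GrayLevelMatrix) -> dict[str, float] | None:
    """Short- and long-run emphasis of one run-length matrix."""
    p = _normalize(m)
    if p is None:
        return None
    _, length = np.nonzero(p)
    pv = p[np.nonzero(p)]
    return {
        "SRE": float(np.sum(pv / length**2)),
        "LRE": float(np.sum(pv * length**2)),
    }


def glzlm_features(m: GrayLevelMatrix) -> dict[str, float] | None:
    """Low- and high-gray-level zone emphasis.

    The distribution is normalised over all zones; level-0 cells are then
    excluded from the sums so that LGZE (which divides by i^2) stays finite.
    """
    p = _normalize(m)
    if p is None:
        return None
    i, j = np.nonzero(p)
    keep = i > 0
    i, pv = i[keep], p[np.nonzero(p)][keep]
    return {
        "LGZE": float(np.sum(pv / i.astype(float) ** 2)),
        "HGZE": float(np.sum(pv * i.astype(float) ** 2)),
    }


def texture_features(d: DiscretizedVOI) -> dict[str, float]:
    """The six textural indices of one discretized VOI.

    GLCM and GLRLM features are unweighted means over the 13 directions;
    directions whose matrix is empty (no voxel pair along that offset) are
    skipped. Raises ``ValueError`` when every direction is degenerate.
    """
    if d.mask.n_voxels < 2:
        raise ValueError("texture features require at least 2 in-mask voxels")
    dirs = direction_set()
    out: dict[str, float] = {}
    for builder, extractor, names in (
        (glcm, glcm_features, ("Homogeneity", "Entropy")),
        (glrlm, glrlm_features, ("SRE", "LRE")),
    ):
        acc = {n: [] for n in names}
        for off in dirs:
            feats = extractor(builder(d, off))
            if feats is None:
                continue
            for n in names:
                acc[n].append(feats[n])
        if not acc[names[0]]:
            raise ValueError(f"degenerate VOI: no {builder.__name__} pairs in any direction")
        for n in names:
            out[n] = float(np.mean(acc[n]))
    zfeats = glzlm_features(glzlm(d))
    if zfeats is None:
        raise ValueError("degenerate VOI: no zones")
    out.update(zfeats)
    return out


def _sphere_kernel(spacing: tuple[float, float, float], volume_mL: float = 1.0) -> np.ndarray:
    """Binary kernel of voxel offsets whose centers lie within the sphere radius."""
    r = sphere_radius_mm(volume_mL)
    half = [int(np.floor(r / s)) for s in spacing]
    axes = [np.arange(-h, h + 1) * s for h, s in zip(half, spacing)]
    d2 = (
        axes[0][:, None, None] ** 2
        + axes[1][None, :, None] ** 2
        + axes[2][None, None, :] ** 2
    )
    return (d2 <= r * r).astype(np.float64)


def suv_peak(vol: PETVolume, mask: VOIMask, sphere_volume_mL: float = 1.0) -> float:
    """Maximum, over in-mask centers, of the mean SUV in a 1 mL sphere.

    Sphere membership is by voxel-center distance; the sphere may extend
    beyond the mask but is truncated at the grid boundary (the mean is taken
    over in-grid sphere voxels).
    """
    kernel = _sphere_kernel(vol.spacing, sphere_volume_mL)
    if kernel.sum() == 0:
        raise ValueError("voxel grid too coarse: the peak sphere contains no voxel")
    num = signal.fftconvolve(vol.data, kernel, mode="same")
    den = signal.fftconvolve(np.ones_like(vol.data), kernel, mode="same")
    means = num / np.maximum(den, 0.5)
    return float(means[mask.data].max())


def conventional_features(vol: PETVolume, mask: VOIMask) -> dict[str, float]:
    """SUVmean, SUVmax, SUVpeak, MV (mL) and TLG (SUV*mL) of one VOI."""
    if mask.shape != vol.shape:
        raise ValueError("mask grid does not match the volume")
    if mask.n_voxels == 0:
        raise ValueError("mask is empty")
    vals = vol.data[mask.data]
    mv = mask.volume_mL
    suv_mean = float(vals.mean())
    return {
        "SUVmean": suv_mean,
        "SUVmax": float(vals.max()),
        "SUVpeak": suv_peak(vol, mask),
        "MV": mv,
        "TLG": suv_mean * mv,
    }


def extract_all(
    vol: PETVolume,
    mask: VOIMask,
    spec: DiscretizationSpec | None = None,
    names: tuple[str, ...] = FEATURE_NAMES,
) -> dict[str, float]:
    """Extract the requested radiomic indices (default: all 11) for one VOI.

    Deterministic for fixed inputs. ``names`` restricts the computation to a
    subset (e.g. only ``("Entropy",)``), skipping unneeded matrices.
    """
    unknown = set(names) - set(FEATURE_NAMES)
    if unknown:
        raise ValueError(f"unknown feature names: {sorted(unknown)}")
    out: dict[str, float] = {}
    if any(n in CONVENTIONAL_NAMES for n in names):
        out.update(conventional_features(vol, mask))
    want_tex = [n for n in names if n in TEXTURE_NAMES]
    if want_tex:
        d = discretize(vol, mask, spec)
        if set(want_tex) == set(TEXTURE_NAMES):
            out.update(texture_features(d))
        else:
            dirs = direction_set()
            if {"Homogeneity", "Entropy"} & set(want_tex):
                feats = [f for f in (glcm_features(glcm(d, o)) for o in dirs) if f]
                if not feats:
                    raise ValueError("degenerate VOI: no co-occurrence pairs")
                for n in ("Homogeneity", "Entropy"):
                    out[n] = float(np.mean([f[n] for f in feats]))
            if {"SRE", "LRE"} & set(want_tex):
                feats = [f for f in (glrlm_features(glrlm(d, o)) for o in dirs) if f]
                for n in ("SRE", "LRE"):
                    out[n] = float(np.mean([f[n] for f in feats]))
            if {"LGZE", "HGZE"} & set(want_tex):
                zf = glzlm_features(glzlm(d))
                if zf is None:
                    raise ValueError("degenerate VOI: no zones")
                out.update(zf)
    return {n: out[n] for n in names}


class RadiomicsExtractor(BaseEstimator, TransformerMixin):
    """Stateless sklearn-style transformer mapping (volume, mask) pairs to the
    11-feature table.

    Parameters
    ----------
    n_bins, lower_bound, upper_bound
        Absolute discretization grid (default 128 levels over [0, 40] SUV).
    """

    def __init__(self, n_bins: int = 128, lower_bound: float = 0.0, upper_bound: float = 40.0):
        self.n_bins = n_bins
        self.lower_bound = lower_bound
        self.upper_bound = upper_bound

    def fit(self, X=None, y=None):
        self.spec_ = DiscretizationSpec(self.n_bins, self.lower_bound, self.upper_bound)
        return self

    def transform(self, X) -> pd.DataFrame:
        """X: iterable of ``(PETVolume, VOIMask)`` pairs -> DataFrame with the
        11 canonical feature columns, one row per pair."""
        if not hasattr(self, "spec_"):
            self.fit()
        rows = [extract_all(vol, mask, self.spec_) for vol, mask in X]
        return pd.DataFrame(rows, columns=list(FEATURE_NAMES))
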
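"""Tumor and reference-region delineation.

Tumors are segmented semi-automatically: within a user-supplied seed region
(a box or hand-drawn mask), every voxel at or above a fixed fraction of the
regional SUVmax is kept, restricted to the 26-connected component containing
the hottest voxel. The component restriction is a reproducible surrogate for
the manual exclusion of nearby physiological uptake (e.g. bladder spill-in).

The liver reference region is a sphere of prescribed physical volume drawn
in a homogeneous area.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .volumes import PETVolume, VOIMask

__all__ = ["segment_tumor", "sphere_voi", "box_seed"]

#: 26-connectivity structuring element shared with the zone matrix.
STRUCTURE_26 = np.ones((3, 3, 3), dtype=bool)


def box_seed(
    vol: PETVolume,
    lo: tuple[int, int, int],
    hi: tuple[int, int, int],
) -> VOIMask:
    """Build a box-shaped seed region from inclusive-exclusive index ranges."""
    data = np.zeros(vol.shape, dtype=bool)
    data[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = True
    return VOIMask(data, vol.spacing, vol.origin)


def segment_tumor(
    vol: PETVolume,
    seed_region: VOIMask,
    threshold_fraction: float = 0.40,
) -> VOIMask:
    """Fixed-threshold tumor segmentation within a seed region.

    Keeps voxels of ``seed_region`` with SUV >= ``threshold_fraction`` times
    the maximum SUV inside the seed (inclusive comparison, so the hottest
    voxel is always kept), then restricts to the 26-connected component that
    contains that hottest voxel.

    Parameters
    ----------
    vol : PETVolume
    seed_region : VOIMask
        Non-empty region enclosing the lesion; same grid as ``vol``.
    threshold_fraction : float
        Fraction of the regional SUVmax, in (0, 1). Default 0.40.
    """
    if seed_region.shape != vol.shape:
        raise ValueError("seed region grid does not match the volume")
    if seed_region.n_voxels == 0:
        raise ValueError("seed region is empty")
    if not (0.0 < threshold_fraction < 1.0):
        raise ValueError(f"threshold_fraction must be in (0, 1), got {threshold_fraction}")

    inside = seed_region.data
    suv = vol.data
    suv_max = suv[inside].max()
    if suv_max <= 0:
        raise ValueError("volume is non-positive everywhere inside the seed region")

    above = inside & (suv >= threshold_fraction * suv_max)
    labels, _ = ndimage.label(above, structure=STRUCTURE_26)
    # argmax voxel inside the seed
    flat = np.where(inside.ravel(), suv.ravel(), -np.inf)
    max_idx = np.unravel_index(int(np.argmax(flat)), vol.shape)
    keep = labels == labels[max_idx]
    return VOIMask(keep, vol.spacing, vol.origin)


def sphere_radius_mm(volume_mL: float) -> float:
    """Radius (mm) of a sphere with the given volume in mL."""
    if volume_mL <= 0:
        raise ValueError(f"volume_mL must be > 0, got {volume_mL}")
    return (3.0 * volume_mL * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)


def sphere_voi(
    vol: PETVolume,
    center_mm: tuple[float, float, float],
    volume_mL: float,
) -> VOIMask:
    """Spherical VOI of prescribed physical volume.

    The mask contains every voxel whose center lies within
    ``r = (3 V / 4 pi)^(1/3)`` of ``center_mm`` (physical coordinates, same
    frame as the volume origin). Raises if the sphere extends outside the
    grid extent.
    """
    r = sphere_radius_mm(volume_mL)
    center = np.asarray(center_mm, dtype=float)
    for c, o, n, s in zip(center, vol.origin, vol.shape, vol.spacing):
        # grid extent in cell terms: [o - s/2, o + (n - 0.5) * s]
        if c - r < o - 0.5 * s or c + r > o + (n - 0.5) * s:
            raise ValueError(
                f"sphere of radius {r:.1f} mm at {tuple(center)} extends outside the grid"
            )
    coords = [
        o + np.arange(n) * s for o, n, s in zip(vol.origin, vol.shape, vol.spacing)
    ]
    dx2 = [(c - cc) ** 2 for c, cc in zip(coords, center)]
    d2 = (
        dx2[0][:, None, None] + dx2[1][None, :, None] + dx2[2][None, None, :]
    )
    return VOIMask(d2 <= r * r, vol.spacing, vol.origin)
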
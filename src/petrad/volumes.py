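"""PET volume containers, NIfTI I/O, SUV conversion and voxel-grid resampling.

Conventions used throughout the package:

* Arrays are indexed ``(x, y, z)`` and voxel coordinates are **voxel-center
  based**: voxel ``i`` along an axis with spacing ``s`` sits at physical
  coordinate ``origin + i * s`` (0-based indices).
* A volume of shape ``n`` with spacing ``s`` covers the physical extent
  ``n * s`` (each voxel owns the cell ``[i*s - s/2, i*s + s/2)`` around its
  center).
* Masks are boolean arrays on the same grid as their parent volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "PETVolume",
    "VOIMask",
    "ScannerProfile",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "convert_to_suv",
    "resample_grid",
    "resample_mask",
]


@dataclass
class PETVolume:
    """A 3D scalar field in SUV units on a regular anisotropic grid.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        SUV values (dimensionless, body-weight normalised).
    spacing : tuple of float
        Voxel edge lengths ``(dx, dy, dz)`` in mm; all positive.
    origin : tuple of float
        Physical position (mm) of the center of voxel ``(0, 0, 0)``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got {self.data.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive lengths, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mL(self) -> float:
        """Volume of one voxel in mL (1 mL = 1000 mm^3)."""
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical extent covered by the grid along each axis (mm)."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))


@dataclass
class VOIMask:
    """A binary volume of interest aligned to a :class:`PETVolume` grid."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D mask, got {self.data.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def volume_mL(self) -> float:
        return self.n_voxels * float(np.prod(self.spacing)) / 1000.0


@dataclass(frozen=True)
class ScannerProfile:
    """Forward model of a PET device: output grid, PSF blur and noise.

    ``psf_fwhm`` is the full width at half maximum (mm) of the Gaussian
    point-spread function; ``noise_level`` is the coefficient of variation of
    the multiplicative reconstruction noise (fraction of the local value).
    """

    name: str
    voxel_size: tuple[float, float, float]
    psf_fwhm: float = 0.0
    noise_level: float = 0.0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        if self.psf_fwhm < 0 or self.noise_level < 0:
            raise ValueError("psf_fwhm and noise_level must be >= 0")


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def read_volume(path: str | Path) -> PETVolume:
    """Read a 3D NIfTI image into a :class:`PETVolume`.

    Spacing is taken from the header zooms and the origin from the affine
    translation. Raises ``FileNotFoundError`` for missing files and
    ``ValueError`` for non-3D images.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(t) for t in img.affine[:3, 3])
    return PETVolume(np.asarray(data, dtype=np.float64), spacing, origin)


def write_volume(vol: PETVolume, path: str | Path) -> None:
    """Write a :class:`PETVolume` as uncompressed/compressed NIfTI."""
    img = nib.Nifti1Image(vol.data.astype(np.float64), _affine(vol.spacing, vol.origin))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def read_mask(path: str | Path) -> VOIMask:
    """Read a binary mask stored as NIfTI (nonzero = inside)."""
    vol = read_volume(path)
    return VOIMask(vol.data > 0.5, vol.spacing, vol.origin)


def write_mask(mask: VOIMask, path: str | Path) -> None:
    """Write a mask as 8-bit 0/1 NIfTI."""
    img = nib.Nifti1Image(
        mask.data.astype(np.uint8), _affine(mask.spacing, mask.origin)
    )
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def convert_to_suv(
    activity: np.ndarray,
    body_weight_kg: float,
    injected_activity_MBq: float,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> PETVolume:
    """Convert an activity-concentration image (Bq/mL) to SUV.

    SUV(v) = activity(v) [Bq/mL] * body weight [g] / injected activity [Bq],
    assuming activity is decay-corrected to injection time and tissue density
    of 1 g/mL. The result is dimensionless.
    """
    if body_weight_kg <= 0:
        raise ValueError(f"body_weight_kg must be > 0, got {body_weight_kg}")
    if injected_activity_MBq <= 0:
        raise ValueError(
            f"injected_activity_MBq must be > 0, got {injected_activity_MBq}"
        )
    activity = np.asarray(activity, dtype=np.float64)
    suv = activity * (body_weight_kg * 1e3) / (injected_activity_MBq * 1e6)
    return PETVolume(suv, spacing, origin)


def _resample_geometry(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    target_spacing: tuple[float, float, float],
):
    """New grid shape and source fractional coordinates per axis.

    The new grid covers the same physical extent (to within one voxel):
    ``n_new = floor(extent / target)``, with new voxel cells aligned to the
    low edge of the source extent. Returns the new shape and, per axis, the
    fractional source index of each new voxel center.
    """
    new_shape = []
    coords = []
    for n, s, t in zip(shape, spacing, target_spacing):
        extent = n * s
        m = int(np.floor(extent / t + 1e-9))
        if m < 1:
            raise ValueError(
                f"target spacing {t} mm exceeds the volume extent {extent} mm"
            )
        new_shape.append(m)
        # new voxel j center at (j + 0.5)*t - 0.5*s relative to the source
        # voxel-0 center -> fractional source index
        coords.append(((np.arange(m) + 0.5) * t - 0.5 * s) / s)
    return tuple(new_shape), coords


def resample_grid(
    vol: PETVolume,
    target_spacing: tuple[float, float, float],
    method: str = "cubic",
) -> PETVolume:
    """Resample a volume onto a new voxel grid by cubic interpolation.

    Separable cubic-spline (order 3) interpolation along all three axes;
    samples falling outside the source support take the nearest edge value.
    The returned grid covers the same physical extent to within one voxel
    and has ``spacing == target_spacing``.
    """
    if method != "cubic":
        raise ValueError(f"unsupported interpolation method: {method!r}")
    target_spacing = tuple(float(t) for t in target_spacing)
    if any(t <= 0 for t in target_spacing):
        raise ValueError(f"target spacing must be positive, got {target_spacing}")
    new_shape, axes = _resample_geometry(vol.shape, vol.spacing, target_spacing)
    grid = np.meshgrid(*axes, indexing="ij")
    out = ndimage.map_coordinates(
        vol.data, np.stack(grid), order=3, mode="nearest"
    )
    new_origin = tuple(
        o + 0.5 * (t - s)
        for o, s, t in zip(vol.origin, vol.spacing, target_spacing)
    )
    return PETVolume(out.reshape(new_shape), target_spacing, new_origin)


def resample_mask(mask: VOIMask, target_spacing: tuple[float, float, float]) -> VOIMask:
    """Transfer a binary mask to a new grid by nearest-neighbor lookup.

    Masks stay strictly binary: each new voxel takes the value of the nearest
    source voxel (no partial volumes), re-binarised at 0.5.
    """
    target_spacing = tuple(float(t) for t in target_spacing)
    new_shape, axes = _resample_geometry(mask.shape, mask.spacing, target_spacing)
    idx = [np.clip(np.round(a).astype(int), 0, n - 1) for a, n in zip(axes, mask.shape)]
    out = mask.data[np.ix_(*idx)]
    new_origin = tuple(
        o + 0.5 * (t - s)
        for o, s, t in zip(mask.origin, mask.spacing, target_spacing)
    )
    return VOIMask(out, target_spacing, new_origin)
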
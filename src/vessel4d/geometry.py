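"""Image-grid geometry, physical/index coordinate maps, and LPS/RAS conventions.

The canonical physical frame throughout the package is ITK-style LPS
(Left-Posterior-Superior).  NIfTI stores its affine in RAS
(Right-Anterior-Superior); the readers/writers here convert at the boundary,
so every coordinate seen by the rest of the package — mesh vertices,
deformation vectors, cutting planes — is LPS millimetres.  Mixing the two
frames is the classic source of silent sign errors when several imaging
toolkits share one workflow, which is why the conversion lives in exactly
one place.

Indices are 0-based, ordered ``(x, y, z)`` to match the physical axes, and
refer to voxel *centers*.  Continuous (fractional) indices are allowed
everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import SimpleITK as sitk

__all__ = [
    "VolumeGeometry",
    "ImageVolume",
    "BinaryMask",
    "index_to_physical",
    "physical_to_index",
    "lps_to_ras",
    "ras_to_lps",
    "read_nifti",
    "write_nifti",
    "read_mask",
    "write_mask",
    "to_sitk",
    "from_sitk",
]

_ORTHO_TOL = 1e-8


@dataclass(frozen=True)
class VolumeGeometry:
    """Physical placement of a 3D voxel grid.

    Parameters
    ----------
    shape : tuple of int
        Voxels per axis, ``(nx, ny, nz)``.
    spacing : tuple of float
        Voxel size in mm per axis; all components positive.
    origin : tuple of float
        Physical (LPS, mm) position of the center of voxel ``(0, 0, 0)``.
    direction : (3, 3) array
        Orthonormal matrix whose *columns* are the physical directions of
        the image axes.  Defaults to identity (axis-aligned grid).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        D = np.asarray(self.direction, dtype=float).reshape(3, 3)
        object.__setattr__(self, "direction", D)
        if len(self.shape) != 3 or any(n <= 0 for n in self.shape):
            raise ValueError(f"shape must be a positive integer triple, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")
        if not np.allclose(D.T @ D, np.eye(3), atol=_ORTHO_TOL):
            raise ValueError("direction matrix is not orthonormal")

    @property
    def affine(self) -> np.ndarray:
        """4x4 LPS index->physical affine (voxel centers)."""
        A = np.eye(4)
        A[:3, :3] = self.direction * np.asarray(self.spacing)
        A[:3, 3] = self.origin
        return A

    @property
    def extent_mm(self) -> np.ndarray:
        """Physical edge lengths of the grid along its own axes."""
        return np.asarray(self.shape) * np.asarray(self.spacing)

    def __eq__(self, other) -> bool:
        if not isinstance(other, VolumeGeometry):
            return NotImplemented
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
            and np.allclose(self.direction, other.direction)
        )


@dataclass
class ImageVolume:
    """A 3D scalar image (HU-like units) on a physical grid.

    ``values`` is indexed ``[ix, iy, iz]`` matching the geometry axes.
    """

    geometry: VolumeGeometry
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.shape != tuple(self.geometry.shape):
            raise ValueError(
                f"array shape {self.values.shape} != geometry shape {self.geometry.shape}"
            )


@dataclass
class BinaryMask:
    """A boolean labelling of a physical grid (foreground = True)."""

    geometry: VolumeGeometry
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values).astype(bool)
        if self.values.shape != tuple(self.geometry.shape):
            raise ValueError(
                f"array shape {self.values.shape} != geometry shape {self.geometry.shape}"
            )

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())


def index_to_physical(geom: VolumeGeometry, index) -> np.ndarray:
    """Map continuous voxel indices to physical LPS mm.

    ``p = origin + direction @ (index * spacing)``.  Accepts a single triple
    or an (N, 3) array.
    """
    idx = np.asarray(index, dtype=float)
    scaled = idx * np.asarray(geom.spacing)
    return np.asarray(geom.origin) + scaled @ geom.direction.T


def physical_to_index(geom: VolumeGeometry, point) -> np.ndarray:
    """Exact inverse of :func:`index_to_physical` (no clamping)."""
    p = np.asarray(point, dtype=float)
    local = (p - np.asarray(geom.origin)) @ geom.direction
    return local / np.asarray(geom.spacing)


def lps_to_ras(point) -> np.ndarray:
    """Negate x and y; z unchanged.  Involution: applying twice is identity."""
    p = np.array(point, dtype=float, copy=True)
    p[..., 0] *= -1
    p[..., 1] *= -1
    return p


# the two conversions are the same sign flip
ras_to_lps = lps_to_ras


# ---------------------------------------------------------------------------
# NIfTI I/O (RAS on disk <-> LPS in memory)
# ---------------------------------------------------------------------------

_FLIP = np.diag([-1.0, -1.0, 1.0, 1.0])


def _geometry_from_ras_affine(affine: np.ndarray, shape) -> VolumeGeometry:
    lps_affine = _FLIP @ np.asarray(affine, dtype=float)
    M = lps_affine[:3, :3]
    spacing = np.linalg.norm(M, axis=0)
    direction = M / spacing
    return VolumeGeometry(
        shape=tuple(shape), spacing=tuple(spacing),
        origin=tuple(lps_affine[:3, 3]), direction=direction,
    )


def _ras_affine_from_geometry(geom: VolumeGeometry) -> np.ndarray:
    return _FLIP @ geom.affine


def read_nifti(path) -> ImageVolume:
    """Read a .nii/.nii.gz scalar volume; geometry converted RAS->LPS."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got ndim={data.ndim}")
    geom = _geometry_from_ras_affine(img.affine, data.shape)
    return ImageVolume(geometry=geom, values=data)


def write_nifti(vol: ImageVolume, path) -> None:
    """Write a scalar volume as NIfTI; geometry converted LPS->RAS."""
    affine = _ras_affine_from_geometry(vol.geometry)
    img = nib.Nifti1Image(np.asarray(vol.values, dtype=np.float64), affine)
    nib.save(img, str(path))


def read_mask(path) -> BinaryMask:
    vol = read_nifti(path)
    return BinaryMask(geometry=vol.geometry, values=vol.values > 0.5)


def write_mask(mask: BinaryMask, path) -> None:
    affine = _ras_affine_from_geometry(mask.geometry)
    img = nib.Nifti1Image(mask.values.astype(np.uint8), affine)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# SimpleITK bridge (ITK is natively LPS; only the array axis order differs)
# ---------------------------------------------------------------------------

def to_sitk(vol: ImageVolume | BinaryMask, dtype=np.float64) -> sitk.Image:
    """Convert to a SimpleITK image (same LPS frame; array transposed to zyx)."""
    arr = np.ascontiguousarray(np.asarray(vol.values, dtype=dtype).transpose(2, 1, 0))
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing(tuple(float(s) for s in vol.geometry.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.geometry.origin))
    img.SetDirection(tuple(vol.geometry.direction.ravel(order="C")))
    return img


def from_sitk(img: sitk.Image) -> ImageVolume:
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    geom = VolumeGeometry(
        shape=arr.shape,
        spacing=img.GetSpacing(),
        origin=img.GetOrigin(),
        direction=np.asarray(img.GetDirection()).reshape(3, 3),
    )
    return ImageVolume(geometry=geom, values=np.asarray(arr, dtype=np.float64))
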
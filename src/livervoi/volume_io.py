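"""NIfTI I/O and the internal voxel-grid model.

Every computation in this package happens on a :class:`VoxelGrid`: a 3-D
array of SUV values on an axis-aligned grid with per-axis spacing in mm.
World coordinates are voxel *centers*; voxel (0, 0, 0) sits at ``origin``.
Anatomical orientation (L/R, A/P, S/I flips in the NIfTI affine) is
deliberately ignored after validation — all quantities computed here
(distances, volumes, local statistics) depend only on spacing magnitudes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

logger = logging.getLogger("livervoi")

__all__ = [
    "VoxelGrid",
    "UnsupportedGeometryError",
    "DimensionalityError",
    "load_volume",
    "save_volume",
]

#: Maximum tolerated off-diagonal magnitude in the affine's rotation block,
#: relative to the column norm, before the geometry is declared unsupported.
AFFINE_SHEAR_TOL = 1e-3


class UnsupportedGeometryError(ValueError):
    """Raised for NIfTI affines with rotation or shear components."""


class DimensionalityError(ValueError):
    """Raised for non-3-D NIfTI payloads."""


@dataclass(frozen=True)
class VoxelGrid:
    """A 3-D scalar SUV field on an anisotropic, axis-aligned voxel lattice.

    Parameters
    ----------
    values
        3-D float64 array of SUV (unitless, body-weight normalized).
    spacing
        Per-axis voxel pitch ``(sx, sy, sz)`` in mm, strictly positive.
    origin
        World coordinate (mm) of the *center* of voxel ``(0, 0, 0)``.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 3:
            raise DimensionalityError(
                f"expected a 3-D volume, got ndim={values.ndim}"
            )
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive mm values, got {spacing}")
        if not np.all(np.isfinite(values)):
            raise ValueError("volume contains non-finite values")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in ml (1 ml = 1000 mm^3)."""
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    def index_to_world(self, index) -> np.ndarray:
        """World coordinate (mm) of the center of voxel ``index``."""
        return np.asarray(self.origin) + np.asarray(index) * np.asarray(self.spacing)

    def world_to_index(self, point_mm) -> np.ndarray:
        """Fractional voxel index of a world point (inverse of index_to_world)."""
        return (np.asarray(point_mm, dtype=float) - np.asarray(self.origin)) / np.asarray(
            self.spacing
        )

    def nearest_index(self, point_mm) -> tuple[int, int, int]:
        """Index of the voxel whose center is nearest to a world point."""
        idx = np.rint(self.world_to_index(point_mm)).astype(int)
        return tuple(int(v) for v in idx)

    def domain_bounds_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Outer edges of the grid (mm): voxel centers plus/minus half spacing."""
        origin = np.asarray(self.origin)
        spacing = np.asarray(self.spacing)
        lo = origin - spacing / 2.0
        hi = origin + (np.asarray(self.shape) - 0.5) * spacing
        return lo, hi


def _validate_affine(affine: np.ndarray, path) -> tuple[np.ndarray, np.ndarray]:
    """Check the rotation block is diagonal up to sign; return |spacing|, origin."""
    rot = affine[:3, :3]
    col_norms = np.linalg.norm(rot, axis=0)
    if np.any(col_norms == 0):
        raise UnsupportedGeometryError(f"degenerate affine in {path}:\n{affine}")
    off = rot - np.diag(np.diag(rot))
    if np.max(np.abs(off) / col_norms) > AFFINE_SHEAR_TOL:
        raise UnsupportedGeometryError(
            f"rotated or sheared affine is not supported ({path}):\n{affine}"
        )
    spacing = np.abs(np.diag(rot))
    origin = affine[:3, 3]
    return spacing, origin


def load_volume(path, *, clamp_negative: bool = True) -> VoxelGrid:
    """Read a NIfTI SUV volume (or mask) into a :class:`VoxelGrid`.

    The affine must be axis-aligned up to per-axis scaling, sign flips and
    translation; anything with rotation/shear above ``AFFINE_SHEAR_TOL`` is
    rejected. Negative voxels (reconstruction artifacts) are clamped to 0
    with a warning so they cannot corrupt local means.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise DimensionalityError(
            f"{path} has ndim={data.ndim}; only 3-D volumes are supported"
        )
    spacing, origin = _validate_affine(np.asarray(img.affine, dtype=float), path)
    data = np.ascontiguousarray(data, dtype=np.float64)
    n_neg = int(np.count_nonzero(data < 0))
    if n_neg:
        if clamp_negative:
            logger.warning(
                "%s: clamped %d negative voxels to 0", path.name, n_neg
            )
            data = np.maximum(data, 0.0)
        else:
            logger.warning("%s: %d negative voxels retained", path.name, n_neg)
    return VoxelGrid(values=data, spacing=tuple(spacing), origin=tuple(origin))


def save_volume(grid: VoxelGrid, path, *, dtype=np.float64) -> None:
    """Write a :class:`VoxelGrid` to NIfTI.

    Files are written as NIfTI-2, whose header carries the affine in
    float64, so float64 payloads *and* their geometry (spacing such as
    4.1 mm is not float32-representable) round-trip losslessly through
    :func:`load_volume`; NIfTI-1 input is read transparently. Pass an
    integer ``dtype`` to store label masks compactly.
    """
    path = Path(path)
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = grid.spacing
    affine[:3, 3] = grid.origin
    data = np.asarray(grid.values, dtype=dtype)
    img = nib.Nifti2Image(data, affine)
    img.header.set_data_dtype(dtype)
    nib.save(img, str(path))
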
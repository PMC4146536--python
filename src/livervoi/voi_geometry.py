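"""Spherical and cuboid VOIs on anisotropic grids, and the liver coordinate.

Spheres are defined in world (mm) coordinates and realized as voxel masks by
closed-ball membership of voxel centers, honoring the per-axis spacing.
The liver coordinate expresses a VOI center as fractions of the edges of a
cuboid that circumscribes the whole liver, which makes inter-study VOI
locations comparable despite different patient positioning; the inter-study
reproducibility metric is the Euclidean distance between two such fractional
coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .volume_io import VoxelGrid

logger = logging.getLogger("livervoi")

__all__ = [
    "SphereVOI",
    "LiverCuboid",
    "LiverCoord",
    "sphere_mask",
    "cuboid_mask",
    "liver_relative_coords",
    "liver_coord_distance",
]


@dataclass(frozen=True)
class SphereVOI:
    """A spherical VOI: world-coordinate center (mm) and diameter (mm)."""

    center_mm: tuple[float, float, float]
    diameter_mm: float

    def __post_init__(self) -> None:
        if not self.diameter_mm > 0:
            raise ValueError(f"diameter must be positive, got {self.diameter_mm}")
        center = tuple(float(c) for c in self.center_mm)
        if len(center) != 3 or not all(np.isfinite(center)):
            raise ValueError(f"center must be a finite mm triple, got {center}")
        object.__setattr__(self, "center_mm", center)
        object.__setattr__(self, "diameter_mm", float(self.diameter_mm))

    @property
    def radius_mm(self) -> float:
        return self.diameter_mm / 2.0


@dataclass(frozen=True)
class LiverCuboid:
    """Axis-aligned cuboid circumscribing the whole liver (mm corners)."""

    corner_min_mm: tuple[float, float, float]
    corner_max_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        lo = tuple(float(c) for c in self.corner_min_mm)
        hi = tuple(float(c) for c in self.corner_max_mm)
        if not all(a < b for a, b in zip(lo, hi)):
            raise ValueError(
                f"degenerate cuboid: corner_min {lo} must be strictly below corner_max {hi}"
            )
        object.__setattr__(self, "corner_min_mm", lo)
        object.__setattr__(self, "corner_max_mm", hi)

    @property
    def edge_lengths_mm(self) -> np.ndarray:
        return np.asarray(self.corner_max_mm) - np.asarray(self.corner_min_mm)


@dataclass(frozen=True)
class LiverCoord:
    """VOI location as unitless fractions of the liver cuboid's edges."""

    r: tuple[float, float, float]

    def __post_init__(self) -> None:
        r = tuple(float(v) for v in self.r)
        if len(r) != 3 or not all(np.isfinite(r)):
            raise ValueError(f"liver coordinate must be a finite triple, got {r}")
        object.__setattr__(self, "r", r)


def _axis_coords(grid: VoxelGrid):
    """Per-axis voxel-center world coordinates (mm)."""
    return [
        grid.origin[ax] + np.arange(grid.shape[ax]) * grid.spacing[ax]
        for ax in range(3)
    ]


def sphere_mask(grid: VoxelGrid, voi: SphereVOI) -> np.ndarray:
    """Boolean mask of voxels whose center lies within the closed ball.

    Membership is Euclidean mm distance <= diameter/2 from the sphere
    center, evaluated with the grid's anisotropic spacing; parts of the
    sphere outside the grid are silently clipped.
    """
    r = voi.radius_mm
    mask = np.zeros(grid.shape, dtype=bool)
    # Bounding slab per axis: voxels further than r along any single axis
    # cannot be inside the ball.
    slices = []
    for ax in range(3):
        lo = int(np.ceil((voi.center_mm[ax] - r - grid.origin[ax]) / grid.spacing[ax]))
        hi = int(np.floor((voi.center_mm[ax] + r - grid.origin[ax]) / grid.spacing[ax]))
        lo = max(lo, 0)
        hi = min(hi, grid.shape[ax] - 1)
        if hi < lo:
            return mask
        slices.append(slice(lo, hi + 1))
    coords = _axis_coords(grid)
    dx = coords[0][slices[0]] - voi.center_mm[0]
    dy = coords[1][slices[1]] - voi.center_mm[1]
    dz = coords[2][slices[2]] - voi.center_mm[2]
    d2 = (
        dx[:, None, None] ** 2
        + dy[None, :, None] ** 2
        + dz[None, None, :] ** 2
    )
    mask[tuple(slices)] = d2 <= r * r
    return mask


def cuboid_mask(grid: VoxelGrid, cuboid: LiverCuboid) -> np.ndarray:
    """Boolean mask of voxel centers inside the closed axis-aligned box."""
    coords = _axis_coords(grid)
    per_axis = [
        (coords[ax] >= cuboid.corner_min_mm[ax]) & (coords[ax] <= cuboid.corner_max_mm[ax])
        for ax in range(3)
    ]
    return (
        per_axis[0][:, None, None]
        & per_axis[1][None, :, None]
        & per_axis[2][None, None, :]
    )


def liver_relative_coords(
    voi_center_mm,
    cuboid: LiverCuboid,
    *,
    corner: str = "min",
) -> LiverCoord:
    """Express a VOI center as fractions of the liver cuboid's edges.

    ``corner`` selects the reference corner the fractions are measured
    from: ``"min"`` (index-minimum corner, the default) or ``"max"``.
    Either convention gives components in [0, 1] for centers inside the
    cuboid, and distances between coordinates are identical under both.
    """
    center = np.asarray(voi_center_mm, dtype=float)
    edges = cuboid.edge_lengths_mm
    if corner == "min":
        r = (center - np.asarray(cuboid.corner_min_mm)) / edges
    elif corner == "max":
        r = (np.asarray(cuboid.corner_max_mm) - center) / edges
    else:
        raise ValueError(f"corner must be 'min' or 'max', got {corner!r}")
    if np.any(r < 0) or np.any(r > 1):
        logger.warning(
            "VOI center %s lies outside the liver cuboid (relative coords %s)",
            tuple(center),
            tuple(r),
        )
    return LiverCoord(r=tuple(r))


def liver_coord_distance(
    r1: LiverCoord,
    r2: LiverCoord,
    *,
    cuboid: LiverCuboid | None = None,
    space: str = "normalized",
) -> float:
    """Euclidean distance between two liver coordinates.

    By default the distance lives in the unitless normalized space the
    coordinates are defined in. With ``space="mm"`` (requires ``cuboid``)
    the componentwise differences are scaled back by the cuboid's edge
    lengths, giving a physical distance in mm.
    """
    diff = np.asarray(r1.r) - np.asarray(r2.r)
    if space == "normalized":
        return float(np.linalg.norm(diff))
    if space == "mm":
        if cuboid is None:
            raise ValueError("space='mm' requires the liver cuboid")
        return float(np.linalg.norm(diff * cuboid.edge_lengths_mm))
    raise ValueError(f"space must be 'normalized' or 'mm', got {space!r}")
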
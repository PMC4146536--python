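"""Minimum-CVv search: the core reference-VOI placement algorithm.

The liver is a large organ with moderately high, comparatively homogeneous
FDG uptake, so the coefficient of variation of SUV over a medium-sized
spherical neighborhood (CVv = local SD / local mean) is lower deep inside
the liver than near organ boundaries or heterogeneous FDG-avid neighbors
(colon, kidney). The algorithm therefore:

1. takes a single manual input — the center of a large search sphere
   (``d_large``, default 150 mm) roughly enclosing the right liver lobe;
2. computes CVv over a spherical neighborhood (``d_medium``, default 80 mm)
   at every candidate voxel in the search sphere;
3. places the 30-mm PERCIST reference VOI at the voxel of minimum CVv and
   reports its mean, SD and the tumor-delineation threshold
   ``mean + k * SD`` (default ``k = 3``).

Local statistics use an FFT convolution of the volume, its square and the
binary spherical kernel; the volume is centered by its first voxel value
beforehand so that a constant image yields exactly zero SD and CVv (which
makes the lexicographic tie-break well defined). The fast path is tested
against a brute-force per-voxel definition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.fft

from .voi_geometry import SphereVOI, sphere_mask
from .volume_io import VoxelGrid

logger = logging.getLogger("livervoi")

__all__ = [
    "LocalStatsMaps",
    "ReferenceReport",
    "NoValidCandidateError",
    "DegenerateImageError",
    "spherical_kernel",
    "local_stats",
    "find_min_cvv",
    "place_reference_voi",
]

#: Defaults: 150-mm search sphere, 80-mm CVv neighborhood,
#: 30-mm reference VOI, mean + 3 SD threshold.
DEFAULT_D_LARGE_MM = 150.0
DEFAULT_D_MEDIUM_MM = 80.0
DEFAULT_D_VOI_MM = 30.0
DEFAULT_K = 3.0

#: Minimum neighborhood size for a defined sample SD.
MIN_NEIGHBORHOOD_VOXELS = 2


class NoValidCandidateError(RuntimeError):
    """No voxel satisfies the candidate constraints (search sphere too
    small, or the reference VOI cannot fit inside the image)."""


class DegenerateImageError(RuntimeError):
    """Every candidate neighborhood is invalid (e.g. nonpositive mean
    everywhere), so CVv has no minimum."""


@dataclass(frozen=True)
class LocalStatsMaps:
    """Per-voxel local mean / SD / CVv over a spherical neighborhood.

    ``cvv_map`` carries ``+inf`` at invalid voxels (neighborhood smaller
    than 2 voxels, nonpositive mean, or outside ``restrict_to``), so a
    plain argmin can never select them.
    """

    mean_map: np.ndarray
    sd_map: np.ndarray
    cvv_map: np.ndarray
    valid_map: np.ndarray
    neighborhood_diameter_mm: float


@dataclass(frozen=True)
class ReferenceReport:
    """Result of one reference-VOI placement run."""

    center_index: tuple[int, int, int]
    center_mm: tuple[float, float, float]
    voi30_mean: float
    voi30_sd: float
    voi30_voxel_count: int
    threshold: float
    min_cvv: float
    params: dict = field(default_factory=dict)
    warnings: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "center_index": list(self.center_index),
            "center_mm": list(self.center_mm),
            "voi30_mean": self.voi30_mean,
            "voi30_sd": self.voi30_sd,
            "voi30_voxel_count": self.voi30_voxel_count,
            "threshold": self.threshold,
            "min_cvv": self.min_cvv,
            "params": dict(self.params),
            "warnings": list(self.warnings),
        }


def spherical_kernel(spacing, diameter_mm: float) -> np.ndarray:
    """Binary closed-ball kernel on the anisotropic voxel lattice.

    Entry (i, j, k) is True when the offset from the kernel center, in mm,
    has Euclidean norm <= diameter/2.
    """
    if not diameter_mm > 0:
        raise ValueError(f"diameter must be positive, got {diameter_mm}")
    r = diameter_mm / 2.0
    half = [int(np.floor(r / s)) for s in spacing]
    offsets = [np.arange(-h, h + 1) * s for h, s in zip(half, spacing)]
    d2 = (
        offsets[0][:, None, None] ** 2
        + offsets[1][None, :, None] ** 2
        + offsets[2][None, None, :] ** 2
    )
    return d2 <= r * r


def _fft_correlate_same(volumes, kernel):
    """Correlate each volume with a centered symmetric kernel ('same' mode).

    The kernel transform is computed once and reused across volumes; all
    kernels here are symmetric, so correlation equals convolution.
    """
    vshape = volumes[0].shape
    kshape = kernel.shape
    fshape = [scipy.fft.next_fast_len(n + m - 1) for n, m in zip(vshape, kshape)]
    kf = scipy.fft.rfftn(kernel.astype(np.float64), fshape)
    out = []
    start = [(m - 1) // 2 for m in kshape]
    sl = tuple(slice(s, s + n) for s, n in zip(start, vshape))
    for vol in volumes:
        vf = scipy.fft.rfftn(vol, fshape)
        full = scipy.fft.irfftn(vf * kf, fshape)
        out.append(np.ascontiguousarray(full[sl]))
    return out


def local_stats(
    grid: VoxelGrid,
    diameter_mm: float,
    restrict_to: np.ndarray | None = None,
) -> LocalStatsMaps:
    """Per-voxel mean, sample SD and CVv over a spherical neighborhood.

    Neighborhoods are clipped at the image boundary (statistics over the
    intersection with the grid domain). Sample SD uses the n-1 denominator.
    Voxels whose neighborhood has fewer than 2 voxels or nonpositive mean
    are invalid; if ``restrict_to`` is given, voxels outside it are
    invalid too (their map entries are still the sentinel values).
    """
    kernel = spherical_kernel(grid.spacing, diameter_mm)
    f = grid.values
    # Center by the first voxel value: variance is shift-invariant, and a
    # constant image then transforms to exact zeros -> exact zero SD/CVv.
    f0 = float(f.flat[0])
    g = f - f0
    ones = np.ones_like(f)
    count_f, sum_g, sumsq_g = _fft_correlate_same([ones, g, g * g], kernel)
    count = np.rint(count_f).astype(np.int64)
    count = np.maximum(count, 1)  # every neighborhood contains its own voxel

    mean = f0 + sum_g / count
    denom = np.maximum(count - 1, 1)
    var = (sumsq_g - sum_g**2 / count) / denom
    np.maximum(var, 0.0, out=var)
    sd = np.sqrt(var)

    valid = (count >= MIN_NEIGHBORHOOD_VOXELS) & (mean > 0)
    if restrict_to is not None:
        if restrict_to.shape != grid.shape:
            raise ValueError(
                f"restrict_to shape {restrict_to.shape} != grid shape {grid.shape}"
            )
        valid &= restrict_to.astype(bool)
    cvv = np.full(grid.shape, np.inf)
    np.divide(sd, mean, out=cvv, where=valid)
    return LocalStatsMaps(
        mean_map=mean,
        sd_map=sd,
        cvv_map=cvv,
        valid_map=valid,
        neighborhood_diameter_mm=float(diameter_mm),
    )


def _voi_fits_mask(grid: VoxelGrid, radius_mm: float, domain: VoxelGrid) -> np.ndarray:
    """Mask of voxels of ``grid`` at which a sphere of ``radius_mm`` lies
    entirely inside the (outer-edge) domain of ``domain``."""
    lo, hi = domain.domain_bounds_mm()
    per_axis = []
    for ax in range(3):
        coords = grid.origin[ax] + np.arange(grid.shape[ax]) * grid.spacing[ax]
        per_axis.append((coords >= lo[ax] + radius_mm) & (coords <= hi[ax] - radius_mm))
    return (
        per_axis[0][:, None, None]
        & per_axis[1][None, :, None]
        & per_axis[2][None, None, :]
    )


def _select_min_cvv(
    search_grid: VoxelGrid,
    voi_large: SphereVOI,
    d_medium_mm: float,
    d_voi_mm: float,
    domain: VoxelGrid,
) -> tuple[tuple[int, int, int], LocalStatsMaps]:
    candidates = sphere_mask(search_grid, voi_large)
    candidates &= _voi_fits_mask(search_grid, d_voi_mm / 2.0, domain)
    if not candidates.any():
        raise NoValidCandidateError(
            "no candidate voxel: the search sphere does not overlap the grid, "
            "or the reference VOI cannot fit inside the image at any of its voxels"
        )
    stats = local_stats(search_grid, d_medium_mm, restrict_to=candidates)
    flat = int(np.argmin(stats.cvv_map))  # first minimum in C order ->
    # lexicographically smallest (i, j, k) on ties
    if not np.isfinite(stats.cvv_map.flat[flat]):
        raise DegenerateImageError(
            "every candidate neighborhood is invalid (nonpositive mean); "
            "the image carries no usable uptake in the search region"
        )
    idx = np.unravel_index(flat, search_grid.shape)
    return tuple(int(v) for v in idx), stats


def find_min_cvv(
    grid: VoxelGrid,
    voi_large: SphereVOI,
    d_medium_mm: float = DEFAULT_D_MEDIUM_MM,
    d_voi_mm: float = DEFAULT_D_VOI_MM,
) -> tuple[int, int, int]:
    """Voxel of minimum CVv among the candidates inside the search sphere.

    Candidates are voxels inside ``voi_large`` whose reference sphere of
    diameter ``d_voi_mm`` fits entirely inside the grid domain (the
    reference statistics must not be truncated by the image border). Ties
    are broken by the lexicographically smallest index, so the result is
    deterministic even on constant images.
    """
    idx, _ = _select_min_cvv(grid, voi_large, d_medium_mm, d_voi_mm, domain=grid)
    return idx


def _crop_for_search(
    grid: VoxelGrid, voi_large: SphereVOI, d_medium_mm: float
) -> tuple[VoxelGrid, tuple[int, int, int]]:
    """Crop to the search sphere dilated by the neighborhood radius.

    Neighborhoods of candidate voxels cannot reach beyond this box, so
    local statistics on the crop equal those on the full grid except where
    the box coincides with a true image boundary (where clipping applies
    identically).
    """
    reach = voi_large.radius_mm + d_medium_mm / 2.0
    lo_idx = []
    slices = []
    for ax in range(3):
        lo = int(np.floor((voi_large.center_mm[ax] - reach - grid.origin[ax]) / grid.spacing[ax])) - 1
        hi = int(np.ceil((voi_large.center_mm[ax] + reach - grid.origin[ax]) / grid.spacing[ax])) + 1
        lo = max(lo, 0)
        hi = min(hi, grid.shape[ax] - 1)
        lo_idx.append(lo)
        slices.append(slice(lo, hi + 1))
    sub = VoxelGrid(
        values=np.ascontiguousarray(grid.values[tuple(slices)]),
        spacing=grid.spacing,
        origin=tuple(grid.index_to_world(lo_idx)),
    )
    return sub, tuple(lo_idx)


def place_reference_voi(
    grid: VoxelGrid,
    voi_large_center_mm,
    *,
    d_large_mm: float = DEFAULT_D_LARGE_MM,
    d_medium_mm: float = DEFAULT_D_MEDIUM_MM,
    d_voi_mm: float = DEFAULT_D_VOI_MM,
    k: float = DEFAULT_K,
) -> ReferenceReport:
    """Run the full placement: CVv search, reference VOI statistics, threshold.

    The only manual input is ``voi_large_center_mm``, the center of the
    search sphere the operator places over the right liver lobe. Returns a
    :class:`ReferenceReport` with the selected center, within-VOI mean and
    sample SD, and the delineation threshold ``mean + k * SD``.
    """
    if not (d_large_mm > 0 and d_medium_mm > 0 and d_voi_mm > 0):
        raise ValueError("all diameters must be positive")
    if d_voi_mm > d_large_mm:
        raise ValueError(
            f"reference VOI diameter {d_voi_mm} mm exceeds the search sphere {d_large_mm} mm"
        )
    if k < 0:
        raise ValueError(f"SD multiplier k must be nonnegative, got {k}")

    voi_large = SphereVOI(center_mm=tuple(voi_large_center_mm), diameter_mm=d_large_mm)
    sub, offset = _crop_for_search(grid, voi_large, d_medium_mm)
    if sub.values.size == 0:
        raise NoValidCandidateError("the search sphere does not overlap the grid")
    sub_idx, stats = _select_min_cvv(sub, voi_large, d_medium_mm, d_voi_mm, domain=grid)
    center_index = tuple(int(s + o) for s, o in zip(sub_idx, offset))
    center_mm = tuple(float(v) for v in grid.index_to_world(center_index))

    voi30 = SphereVOI(center_mm=center_mm, diameter_mm=d_voi_mm)
    mask30 = sphere_mask(grid, voi30)
    vals = grid.values[mask30]
    voi30_mean = float(np.mean(vals))
    voi30_sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    threshold = voi30_mean + k * voi30_sd

    warnings: list[str] = []
    if voi30_mean <= 0:
        warnings.append("reference VOI mean is nonpositive; threshold is unreliable")
    logger.info(
        "reference VOI at index %s (%.1f, %.1f, %.1f) mm; mean=%.4f SD=%.4f "
        "threshold=%.4f min_cvv=%.5f",
        center_index, *center_mm, voi30_mean, voi30_sd, threshold,
        stats.cvv_map[sub_idx],
    )
    return ReferenceReport(
        center_index=center_index,
        center_mm=center_mm,
        voi30_mean=voi30_mean,
        voi30_sd=voi30_sd,
        voi30_voxel_count=int(np.count_nonzero(mask30)),
        threshold=float(threshold),
        min_cvv=float(stats.cvv_map[sub_idx]),
        params={
            "d_large_mm": float(d_large_mm),
            "d_medium_mm": float(d_medium_mm),
            "d_voi_mm": float(d_voi_mm),
            "k": float(k),
            "tie_break": "lexicographic-smallest-index",
            "voi_large_center_mm": [float(c) for c in voi_large_center_mm],
        },
        warnings=tuple(warnings),
    )
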
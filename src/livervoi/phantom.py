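"""Synthetic FDG PET phantoms with ground-truth organ labels.

The generator emulates the statistical structure the minimum-CVv search
relies on: a large liver-like ellipsoid of moderately high, homogeneous
uptake (SUV ~= 2.5), flanked by a low-uptake lung region, hot
heterogeneous abdominal structures (kidney/colon-like, SUV 3-6), soft
tissue background (SUV ~= 1.0), and optional hyperintense tumors.
Voxel noise is additive Gaussian applied before a Gaussian point-spread
blur (default 8.4 mm FWHM), mimicking reconstruction smoothing. Every
voxel carries exactly one ground-truth label, so placement success and
volume recovery can be scored without human readers.

Label codes: 0 background, 1 lung, 2 liver, 3 hot organ, 10+i for tumor i.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .voi_geometry import LiverCuboid
from .volume_io import VoxelGrid

__all__ = [
    "Ellipsoid",
    "Tumor",
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "paired_study",
    "liver_cuboid_from_labels",
    "LABEL_BACKGROUND",
    "LABEL_LUNG",
    "LABEL_LIVER",
    "LABEL_HOT",
    "TUMOR_LABEL_BASE",
]

LABEL_BACKGROUND = 0
LABEL_LUNG = 1
LABEL_LIVER = 2
LABEL_HOT = 3
TUMOR_LABEL_BASE = 10

#: FWHM of a Gaussian = 2*sqrt(2*ln 2) * sigma.
FWHM_TO_SIGMA = 1.0 / 2.3548200450309493


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid: center and semi-axes in mm, uniform SUV."""

    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]
    suv: float

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes_mm):
            raise ValueError(f"semi-axes must be positive, got {self.semi_axes_mm}")
        if self.suv < 0:
            raise ValueError(f"SUV must be nonnegative, got {self.suv}")


@dataclass(frozen=True)
class Tumor:
    """Spherical hyperintense lesion: center mm, diameter mm, uniform SUV."""

    center_mm: tuple[float, float, float]
    diameter_mm: float
    suv: float

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ValueError(f"tumor diameter must be positive, got {self.diameter_mm}")
        if self.suv < 0:
            raise ValueError(f"tumor SUV must be nonnegative, got {self.suv}")


def _default_hot_organs() -> tuple[Ellipsoid, ...]:
    # A kidney-like hot sphere abutting the liver's anterior-medial face and
    # a colon-like cluster of blobs of mixed intensity below the liver: the
    # heterogeneous, FDG-avid neighborhood the CVv search must avoid.
    return (
        Ellipsoid(center_mm=(260.0, 200.0, 80.0), semi_axes_mm=(30.0, 30.0, 28.0), suv=4.5),
        Ellipsoid(center_mm=(330.0, 300.0, 45.0), semi_axes_mm=(24.0, 24.0, 18.0), suv=3.5),
        Ellipsoid(center_mm=(355.0, 325.0, 55.0), semi_axes_mm=(20.0, 20.0, 16.0), suv=6.0),
        Ellipsoid(center_mm=(308.0, 332.0, 40.0), semi_axes_mm=(20.0, 20.0, 15.0), suv=4.5),
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic study; the seed fixes everything."""

    shape: tuple[int, int, int] = (168, 168, 108)
    spacing: tuple[float, float, float] = (4.1, 4.1, 2.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    background_suv: float = 1.0
    liver: Ellipsoid = Ellipsoid(
        center_mm=(260.0, 280.0, 108.0), semi_axes_mm=(75.0, 60.0, 50.0), suv=2.5
    )
    lung: Ellipsoid = Ellipsoid(
        center_mm=(260.0, 280.0, 185.0), semi_axes_mm=(85.0, 75.0, 27.0), suv=0.5
    )
    hot_organs: tuple[Ellipsoid, ...] = field(default_factory=_default_hot_organs)
    tumors: tuple[Tumor, ...] = ()
    noise_sd: float = 0.2
    psf_fwhm_mm: float = 8.4
    seed: int = 0

    def with_(self, **changes) -> "PhantomSpec":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth of a generated phantom: the quantities tests score against."""

    seed: int
    organ_suv: dict
    liver_voxel_count: int
    tumor_voxel_counts: tuple[int, ...]
    tumor_volumes_ml: tuple[float, ...]
    voxel_volume_ml: float
    noise_sd: float
    psf_fwhm_mm: float

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "organ_suv": dict(self.organ_suv),
            "liver_voxel_count": self.liver_voxel_count,
            "tumor_voxel_counts": list(self.tumor_voxel_counts),
            "tumor_volumes_ml": list(self.tumor_volumes_ml),
            "voxel_volume_ml": self.voxel_volume_ml,
            "noise_sd": self.noise_sd,
            "psf_fwhm_mm": self.psf_fwhm_mm,
        }


def _axis_coords(spec: PhantomSpec):
    return [
        spec.origin[ax] + np.arange(spec.shape[ax]) * spec.spacing[ax]
        for ax in range(3)
    ]


def _ellipsoid_mask(spec: PhantomSpec, ell: Ellipsoid) -> np.ndarray:
    coords = _axis_coords(spec)
    u = [
        (coords[ax] - ell.center_mm[ax]) / ell.semi_axes_mm[ax] for ax in range(3)
    ]
    return (
        u[0][:, None, None] ** 2 + u[1][None, :, None] ** 2 + u[2][None, None, :] ** 2
    ) <= 1.0


def _sphere_mask_mm(spec: PhantomSpec, center, diameter) -> np.ndarray:
    r = diameter / 2.0
    return _ellipsoid_mask(
        spec, Ellipsoid(center_mm=tuple(center), semi_axes_mm=(r, r, r), suv=0.0)
    )


def _check_bounds(spec: PhantomSpec) -> None:
    lo = np.asarray(spec.origin) - np.asarray(spec.spacing) / 2.0
    hi = lo + np.asarray(spec.shape) * np.asarray(spec.spacing)
    offenders = []
    named = [("liver", spec.liver), ("lung", spec.lung)] + [
        (f"hot_organ[{i}]", h) for i, h in enumerate(spec.hot_organs)
    ]
    for name, ell in named:
        c, a = np.asarray(ell.center_mm), np.asarray(ell.semi_axes_mm)
        if np.any(c - a < lo) or np.any(c + a > hi):
            offenders.append(name)
    for i, t in enumerate(spec.tumors):
        c = np.asarray(t.center_mm)
        r = t.diameter_mm / 2.0
        if np.any(c - r < lo) or np.any(c + r > hi):
            offenders.append(f"tumor[{i}]")
    if offenders:
        raise ValueError(f"structures out of grid bounds: {', '.join(offenders)}")


def generate_phantom(spec: PhantomSpec) -> tuple[VoxelGrid, VoxelGrid, PhantomTruth]:
    """Render one phantom: (SUV volume, label volume, ground truth).

    The organ map is piecewise constant; independent Gaussian voxel noise
    (SD ``noise_sd``) is added, then the volume is blurred with a Gaussian
    point-spread of ``psf_fwhm_mm`` FWHM per axis. Output is fully
    deterministic given the spec (including its seed). Labels are painted
    background -> lung -> liver -> hot organs -> tumors, later wins.
    """
    _check_bounds(spec)
    values = np.full(spec.shape, float(spec.background_suv))
    labels = np.full(spec.shape, LABEL_BACKGROUND, dtype=np.int16)

    for label, ell in [(LABEL_LUNG, spec.lung), (LABEL_LIVER, spec.liver)]:
        m = _ellipsoid_mask(spec, ell)
        values[m] = ell.suv
        labels[m] = label
    for ell in spec.hot_organs:
        m = _ellipsoid_mask(spec, ell)
        values[m] = ell.suv
        labels[m] = LABEL_HOT
    tumor_counts = []
    for i, t in enumerate(spec.tumors):
        m = _sphere_mask_mm(spec, t.center_mm, t.diameter_mm)
        values[m] = t.suv
        labels[m] = TUMOR_LABEL_BASE + i
        tumor_counts.append(int(np.count_nonzero(m)))

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    if spec.psf_fwhm_mm > 0:
        sigma_vox = [
            spec.psf_fwhm_mm * FWHM_TO_SIGMA / s for s in spec.spacing
        ]
        values = gaussian_filter(values, sigma=sigma_vox, mode="nearest")
    np.maximum(values, 0.0, out=values)

    grid = VoxelGrid(values=values, spacing=spec.spacing, origin=spec.origin)
    label_grid = VoxelGrid(
        values=labels.astype(np.float64), spacing=spec.spacing, origin=spec.origin
    )
    vv = grid.voxel_volume_ml
    truth = PhantomTruth(
        seed=spec.seed,
        organ_suv={
            "background": spec.background_suv,
            "lung": spec.lung.suv,
            "liver": spec.liver.suv,
            "hot_organs": [h.suv for h in spec.hot_organs],
            "tumors": [t.suv for t in spec.tumors],
        },
        liver_voxel_count=int(np.count_nonzero(labels == LABEL_LIVER)),
        tumor_voxel_counts=tuple(tumor_counts),
        tumor_volumes_ml=tuple(c * vv for c in tumor_counts),
        voxel_volume_ml=vv,
        noise_sd=spec.noise_sd,
        psf_fwhm_mm=spec.psf_fwhm_mm,
    )
    return grid, label_grid, truth


def _shift(point, offset):
    return tuple(float(p + o) for p, o in zip(point, offset))


def paired_study(
    spec: PhantomSpec,
    seed_pair: tuple[int, int],
    tumor_change: float = 1.0,
    max_offset_mm: float = 5.0,
):
    """Two studies of the same synthetic subject.

    The second study differs by an independent noise realization, a small
    random rigid body offset (magnitude <= ``max_offset_mm``, drawn from
    the second seed) applied to every structure, and tumor diameters
    rescaled so the true tumor volume changes by ``tumor_change``.
    Returns two ``(grid, labels, truth)`` triples.
    """
    if tumor_change <= 0:
        raise ValueError(f"tumor volume scale factor must be positive, got {tumor_change}")
    s1, s2 = seed_pair
    first = generate_phantom(spec.with_(seed=int(s1)))

    rng = np.random.default_rng(int(s2))
    direction = rng.normal(size=3)
    norm = np.linalg.norm(direction)
    direction = direction / norm if norm > 0 else np.zeros(3)
    offset = direction * rng.uniform(0.0, max_offset_mm)

    diam_scale = tumor_change ** (1.0 / 3.0)
    spec2 = spec.with_(
        seed=int(s2),
        liver=dataclasses.replace(spec.liver, center_mm=_shift(spec.liver.center_mm, offset)),
        lung=dataclasses.replace(spec.lung, center_mm=_shift(spec.lung.center_mm, offset)),
        hot_organs=tuple(
            dataclasses.replace(h, center_mm=_shift(h.center_mm, offset))
            for h in spec.hot_organs
        ),
        tumors=tuple(
            dataclasses.replace(
                t,
                center_mm=_shift(t.center_mm, offset),
                diameter_mm=t.diameter_mm * diam_scale,
            )
            for t in spec.tumors
        ),
    )
    second = generate_phantom(spec2)
    return first, second


def liver_cuboid_from_labels(label_grid: VoxelGrid) -> LiverCuboid:
    """Tight axis-aligned cuboid around the liver label (voxel centers, mm)."""
    liver = label_grid.values == LABEL_LIVER
    if not liver.any():
        raise ValueError("label volume contains no liver voxels")
    idx = np.argwhere(liver)
    lo = label_grid.index_to_world(idx.min(axis=0))
    hi = label_grid.index_to_world(idx.max(axis=0))
    return LiverCuboid(corner_min_mm=tuple(lo), corner_max_mm=tuple(hi))
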
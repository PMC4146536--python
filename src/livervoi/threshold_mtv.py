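"""Threshold-based tumor delineation, MTV, TLG and inter-study change.

The delineation threshold is derived from the liver reference VOI as
``mean + k * SD`` (default ``k = 3``). Within expert-agreed candidate tumor
regions, every voxel with SUV *strictly* above the threshold is tumor.
MTV (metabolic tumor volume, ml) is the total volume of tumor voxels; TLG
(total lesion glycolysis) is tumor mean SUV times MTV. Candidate regions
are an explicit input: separating tumor uptake from adjacent physiologic
uptake is an expert judgement this package does not automate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume_io import VoxelGrid

__all__ = [
    "TumorSegmentation",
    "UndefinedBaselineError",
    "liver_threshold",
    "percist_measurability_threshold",
    "delineate",
    "total_lesion_glycolysis",
    "relative_change",
]


class UndefinedBaselineError(ValueError):
    """Relative change is undefined when the baseline MTV is zero."""


@dataclass(frozen=True)
class TumorSegmentation:
    """Thresholded tumor mask with per-region and total volumes."""

    tumor_mask: np.ndarray
    per_region_volumes_ml: tuple[tuple[int, float], ...]
    mtv_ml: float
    tlg: float
    threshold_used: float

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold_used,
            "mtv_ml": self.mtv_ml,
            "tlg": self.tlg,
            "per_region": [
                {"label": int(lab), "volume_ml": vol}
                for lab, vol in self.per_region_volumes_ml
            ],
        }


def liver_threshold(voi30_mean: float, voi30_sd: float, k: float = 3.0) -> float:
    """Delineation threshold from the liver reference VOI: mean + k*SD."""
    if voi30_sd < 0:
        raise ValueError(f"SD must be nonnegative, got {voi30_sd}")
    if k < 0:
        raise ValueError(f"k must be nonnegative, got {k}")
    return float(voi30_mean + k * voi30_sd)


def percist_measurability_threshold(voi30_mean: float, voi30_sd: float) -> float:
    """PERCIST 1.0 lesion-measurability level, 1.5*mean + 2*SD.

    An alternative reference level; not the delineation threshold this
    package uses by default.
    """
    if voi30_sd < 0:
        raise ValueError(f"SD must be nonnegative, got {voi30_sd}")
    return float(1.5 * voi30_mean + 2.0 * voi30_sd)


def delineate(
    grid: VoxelGrid, candidate_regions: np.ndarray, threshold: float
) -> TumorSegmentation:
    """Threshold the volume inside candidate tumor regions.

    ``candidate_regions`` is an integer label volume (0 = not a candidate).
    A voxel is tumor when its SUV is strictly greater than ``threshold``
    and its label is positive; a voxel exactly at the threshold is
    excluded. Volumes are reported per candidate label and in total (ml).
    """
    candidate_regions = np.asarray(candidate_regions)
    if candidate_regions.shape != grid.shape:
        raise ValueError(
            f"candidate regions shape {candidate_regions.shape} != grid shape {grid.shape}"
        )
    if not np.isfinite(threshold):
        # -inf is allowed and returns the candidate regions themselves
        if not threshold == -np.inf:
            raise ValueError(f"threshold must be finite or -inf, got {threshold}")
    labels = candidate_regions.astype(np.int64)
    tumor_mask = (grid.values > threshold) & (labels > 0)
    vv = grid.voxel_volume_ml
    per_region = []
    for lab in np.unique(labels[labels > 0]):
        n = int(np.count_nonzero(tumor_mask & (labels == lab)))
        per_region.append((int(lab), n * vv))
    mtv_ml = float(np.count_nonzero(tumor_mask) * vv)
    if tumor_mask.any():
        tlg = float(np.mean(grid.values[tumor_mask]) * mtv_ml)
    else:
        tlg = 0.0
    return TumorSegmentation(
        tumor_mask=tumor_mask,
        per_region_volumes_ml=tuple(per_region),
        mtv_ml=mtv_ml,
        tlg=tlg,
        threshold_used=float(threshold),
    )


def total_lesion_glycolysis(seg: TumorSegmentation, grid: VoxelGrid) -> float:
    """TLG = tumor mean SUV x MTV (SUV*ml); 0 for an empty mask."""
    if not seg.tumor_mask.any():
        return 0.0
    return float(np.mean(grid.values[seg.tumor_mask]) * seg.mtv_ml)


def relative_change(mtv_first: float, mtv_second: float) -> float:
    """Inter-study relative MTV change in percent.

    Defined as ``(second - first) / first * 100``; only meaningful for
    subjects with measurable tumor at baseline (``mtv_first > 0``).
    """
    if mtv_first <= 0:
        raise UndefinedBaselineError(
            f"baseline MTV must be positive, got {mtv_first}"
        )
    return float((mtv_second - mtv_first) / mtv_first * 100.0)
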
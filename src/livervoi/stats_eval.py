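"""Agreement and comparison statistics, plus the phantom batch experiment.

Agreement between two raters/methods is summarized by the two-way,
absolute-agreement, single-measure intraclass correlation ICC(2,1) with a
bootstrap CI, and by Bland-Altman bias and limits of agreement (mean
difference +/- 2 SD of the differences, matching the convention used for
the reported figures rather than 1.96 SD). Paired comparisons use the
classical paired t-test; families of P-values are adjusted with Holm's
step-down method.

``batch_experiment`` is the in-silico analog of a multi-reader clinical
evaluation: over a batch of phantom seeds it scores reference-VOI
placement success against ground-truth labels, run-to-run voxel agreement
under jittered search-sphere placement, and inter-run distance in the
liver coordinate, per CVv-neighborhood diameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from . import cvv_search
from .phantom import (
    LABEL_LIVER,
    PhantomSpec,
    generate_phantom,
    liver_cuboid_from_labels,
)
from .voi_geometry import (
    SphereVOI,
    liver_coord_distance,
    liver_relative_coords,
    sphere_mask,
)

__all__ = [
    "AgreementResult",
    "InsufficientDataError",
    "DegenerateVarianceError",
    "icc_agreement",
    "holm_adjust",
    "paired_t",
    "bland_altman_plot",
    "batch_experiment",
]


class InsufficientDataError(ValueError):
    """Fewer than two pairs: agreement statistics are undefined."""


class DegenerateVarianceError(ValueError):
    """Zero variance where a test statistic requires some."""


@dataclass(frozen=True)
class AgreementResult:
    """ICC(2,1) plus Bland-Altman summary for paired measurements."""

    icc: float
    icc_ci: tuple[float, float]
    bias: float
    loa: tuple[float, float]
    n: int
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "icc": self.icc,
            "icc_ci": list(self.icc_ci),
            "bias": self.bias,
            "loa": list(self.loa),
            "n": self.n,
            "degenerate": self.degenerate,
        }


def _icc2_1(data: np.ndarray) -> float:
    """ICC(2,1) from the two-way ANOVA mean squares.

    data: (n subjects) x (k raters). Returns nan when the ANOVA
    decomposition is fully degenerate (zero everywhere).
    """
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((data - grand) ** 2)
    sse = max(sst - ssr - ssc, 0.0)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0.0:
        return np.nan
    return (msr - mse) / denom


def icc_agreement(
    pairs,
    *,
    n_boot: int = 2000,
    seed: int = 0,
) -> AgreementResult:
    """Two-way absolute-agreement single-measure ICC with bootstrap CI.

    ``pairs`` is a sequence of (a, b) measurements of the same subjects by
    two raters/methods. The CI is a percentile bootstrap over subjects
    (``n_boot`` replicates, seeded). Identical vectors are a degenerate
    case reported as perfect agreement (ICC 1).
    """
    data = np.asarray(pairs, dtype=float)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError(f"expected an (n, 2) array of pairs, got shape {data.shape}")
    n = data.shape[0]
    if n < 2:
        raise InsufficientDataError(f"need at least 2 pairs, got {n}")
    if not np.all(np.isfinite(data)):
        raise ValueError("pairs contain non-finite values")

    diff = data[:, 1] - data[:, 0]
    bias = float(diff.mean())
    sd_diff = float(diff.std(ddof=1))
    loa = (bias - 2.0 * sd_diff, bias + 2.0 * sd_diff)

    if np.array_equal(data[:, 0], data[:, 1]):
        icc = 1.0
        degenerate = bool(np.ptp(data) == 0)
        return AgreementResult(
            icc=icc, icc_ci=(1.0, 1.0), bias=bias, loa=loa, n=n, degenerate=degenerate
        )

    icc = _icc2_1(data)
    degenerate = not np.isfinite(icc)
    if degenerate:
        icc = 1.0  # zero total variance can only arise from identical data

    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        sample = data[rng.integers(0, n, size=n)]
        if np.array_equal(sample[:, 0], sample[:, 1]):
            boots.append(1.0)
            continue
        val = _icc2_1(sample)
        if np.isfinite(val):
            boots.append(val)
    if boots:
        ci = tuple(np.percentile(boots, [2.5, 97.5]))
    else:
        ci = (np.nan, np.nan)
    return AgreementResult(
        icc=float(icc),
        icc_ci=(float(ci[0]), float(ci[1])),
        bias=bias,
        loa=loa,
        n=n,
        degenerate=degenerate,
    )


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted P-values, in the input order, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a nonempty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError(f"P-values must lie in [0, 1], got {p}")
    return multipletests(p, method="holm")[1]


def paired_t(pairs) -> tuple[float, float]:
    """Classical two-sided paired t-test; returns (t, p)."""
    data = np.asarray(pairs, dtype=float)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError(f"expected an (n, 2) array of pairs, got shape {data.shape}")
    if data.shape[0] < 2:
        raise InsufficientDataError(f"need at least 2 pairs, got {data.shape[0]}")
    diff = data[:, 1] - data[:, 0]
    if np.ptp(diff) == 0 and diff[0] != 0:
        # constant nonzero difference: t is infinite
        raise DegenerateVarianceError("differences have zero variance")
    if np.ptp(diff) == 0:
        raise DegenerateVarianceError("differences are identically zero")
    res = sps.ttest_rel(data[:, 1], data[:, 0])
    return float(res.statistic), float(res.pvalue)


def bland_altman_plot(pairs, ax=None, units: str = ""):
    """Bland-Altman scatter: mean vs difference, bias and +/-2 SD limits."""
    import matplotlib.pyplot as plt

    data = np.asarray(pairs, dtype=float)
    mean = data.mean(axis=1)
    diff = data[:, 1] - data[:, 0]
    bias = diff.mean()
    sd = diff.std(ddof=1)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(mean, diff, s=18)
    ax.axhline(bias, color="k")
    for lim in (bias - 2 * sd, bias + 2 * sd):
        ax.axhline(lim, color="k", linestyle="--")
    ax.set_xlabel(f"mean of methods {units}".strip())
    ax.set_ylabel(f"difference (second - first) {units}".strip())
    return ax


# ---------------------------------------------------------------------------
# Phantom batch experiment
# ---------------------------------------------------------------------------


def _run_placement(grid, labels, cuboid, center_mm, d_medium_mm, d_large_mm, d_voi_mm, k):
    report = cvv_search.place_reference_voi(
        grid,
        center_mm,
        d_large_mm=d_large_mm,
        d_medium_mm=d_medium_mm,
        d_voi_mm=d_voi_mm,
        k=k,
    )
    mask30 = sphere_mask(grid, SphereVOI(report.center_mm, d_voi_mm))
    inside_liver = bool(np.all(labels.values[mask30] == LABEL_LIVER))
    coord = liver_relative_coords(report.center_mm, cuboid)
    return report, inside_liver, coord


def batch_experiment(
    spec: PhantomSpec,
    seeds,
    d_medium_list=(40.0, 80.0),
    *,
    jitter_mm: float = 10.0,
    d_large_mm: float = cvv_search.DEFAULT_D_LARGE_MM,
    d_voi_mm: float = cvv_search.DEFAULT_D_VOI_MM,
    k: float = cvv_search.DEFAULT_K,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Placement reproducibility over a phantom batch, per neighborhood size.

    For each seed a phantom is generated and the placement is run twice
    with the search-sphere center jittered independently (uniform within
    +/- ``jitter_mm`` per axis, seeded) around the true liver center — the
    analog of two operators placing the search sphere. Per run, success
    means the reference VOI lies fully inside the liver label; per seed
    the two runs are compared by selected voxel and by distance in the
    liver coordinate (from the ground-truth liver bounding cuboid).

    Returns ``(summary, runs)``: one summary row per ``d_medium`` and the
    full per-seed table.
    """
    rows = []
    for seed in seeds:
        seed = int(seed)
        grid, labels, _ = generate_phantom(spec.with_(seed=seed))
        cuboid = liver_cuboid_from_labels(labels)
        rng = np.random.default_rng(seed + 1_000_003)
        jitters = rng.uniform(-jitter_mm, jitter_mm, size=(2, 3))
        centers = [np.asarray(spec.liver.center_mm) + j for j in jitters]
        for d_medium in d_medium_list:
            results = [
                _run_placement(
                    grid, labels, cuboid, c, d_medium, d_large_mm, d_voi_mm, k
                )
                for c in centers
            ]
            (rep1, in1, c1), (rep2, in2, c2) = results
            rows.append(
                {
                    "seed": seed,
                    "d_medium_mm": float(d_medium),
                    "run1_inside_liver": in1,
                    "run2_inside_liver": in2,
                    "same_voxel": rep1.center_index == rep2.center_index,
                    "liver_coord_distance": liver_coord_distance(c1, c2),
                    "voi30_mean": 0.5 * (rep1.voi30_mean + rep2.voi30_mean),
                    "threshold": 0.5 * (rep1.threshold + rep2.threshold),
                    "min_cvv": 0.5 * (rep1.min_cvv + rep2.min_cvv),
                }
            )
    runs = pd.DataFrame(rows)
    summary = (
        runs.groupby("d_medium_mm")
        .apply(
            lambda g: pd.Series(
                {
                    "n_seeds": len(g),
                    "success_count": int(
                        g["run1_inside_liver"].sum() + g["run2_inside_liver"].sum()
                    ),
                    "n_runs": 2 * len(g),
                    "success_rate": (
                        g["run1_inside_liver"].sum() + g["run2_inside_liver"].sum()
                    )
                    / (2 * len(g)),
                    "same_voxel_rate": g["same_voxel"].mean(),
                    "mean_voi30_mean": g["voi30_mean"].mean(),
                    "mean_threshold": g["threshold"].mean(),
                    "mean_interrun_distance": g["liver_coord_distance"].mean(),
                }
            ),
            include_groups=False,
        )
        .reset_index()
    )
    return summary, runs
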
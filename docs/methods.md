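# Methods

## Model and procedure

`livervoi` automates the PERCIST liver reference: a 30-mm spherical VOI in
the right liver lobe whose mean and SD define the tumor-delineation
threshold. The placement criterion is local homogeneity. For each voxel v
the coefficient of variation CVv(v) = SD/mean of SUV is computed over a
spherical neighborhood of diameter `d_medium` centered at v; the reference
VOI (diameter `d_voi`) is centered at the voxel of minimum CVv within a
manually placed search sphere (diameter `d_large`). The threshold is
`mean + k * SD` of the reference VOI. Tumor voxels are those strictly above
the threshold inside explicit candidate-region masks; MTV is their summed
volume in ml, TLG is tumor mean SUV times MTV, and inter-study response is
`(MTV2 - MTV1)/MTV1 * 100` (undefined when the baseline is zero).

Assumptions: the image is an axis-aligned SUV grid (anisotropic spacing in
mm); the liver is the largest homogeneous moderately-avid structure inside
the search sphere; candidate tumor regions are supplied by the user
(separating tumor from adjacent physiologic uptake is expert judgement and
is not automated).

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `d_large_mm` | 150 | mm | search-sphere diameter; the single manual input is its center |
| `d_medium_mm` | 80 | mm | CVv neighborhood; 40–120 mm supported, 80 mm is the most robust (small neighborhoods produce many local CVv minima near the liver periphery, very large ones drag the minimum outside the liver) |
| `d_voi_mm` | 30 | mm | reference VOI diameter per PERCIST |
| `k` | 3 | — | SD multiplier of the threshold (`percist_measurability_threshold` offers the alternative 1.5·mean + 2·SD level) |

All geometry is defined in world mm on voxel centers; spheres use closed-
ball membership (distance ≤ d/2 under the anisotropic metric), so boundary
voxels are included consistently everywhere.

## Numerical choices

- **Local statistics.** Mean, sample SD (n−1 denominator; the convention is
  immaterial at thousands of voxels but must be fixed for oracle tests) and
  CVv are computed by FFT correlation of the image, its square, and the
  binary spherical kernel (`scipy.fft`, real transforms, kernel transform
  reused). The image is first centered by its first voxel value: variance
  is shift-invariant, and a constant image then transforms to exact zeros,
  giving exactly zero SD/CVv — which makes the tie-break well defined.
  Counts are rounded to integers; variances are clipped at zero. The fast
  path must agree with a brute-force nested-loop implementation to 1e-9
  absolute (tested on random anisotropic grids up to 24³).
- **Validity.** Neighborhoods are clipped at the image border (statistics
  over the intersection). Neighborhoods with fewer than 2 voxels or with
  nonpositive mean (air) carry a +inf CVv sentinel and can never win the
  argmin. Candidate centers must additionally keep the *reference* VOI
  fully inside the image, since the reference statistics must not be
  truncated; `d_medium` neighborhoods are not so constrained, and the
  search sphere may extend past the liver or the image.
- **Tie-break.** Minimum CVv ties resolve to the lexicographically
  smallest (i, j, k) — the first minimum in C order — so results are
  deterministic across runs and platforms even on constant images.
- **Cropping.** `place_reference_voi` computes statistics on the search
  sphere's bounding box dilated by the neighborhood radius; neighborhoods
  of candidate voxels cannot reach further, so results equal the full-grid
  computation while the placement runs in ~0.4 s on a 168×168×108 grid.
- **Scale behavior.** CVv is invariant under global intensity scaling, so
  the selected voxel is scale-free and the threshold scales exactly with
  the image.
- **I/O.** Volumes are NIfTI; affines must be diagonal up to sign flips
  and translation (rotation/shear beyond 1e-3 is rejected — resampling is
  out of scope). Orientation flips are ignored after validation because
  every quantity depends only on spacing magnitudes. Files are written as
  NIfTI-2: its float64 header round-trips geometry such as 4.1-mm spacing
  exactly, which the float32 NIfTI-1 header cannot. Negative SUV voxels
  (reconstruction artifacts) are clamped to zero with a warning so they
  cannot corrupt local means.

## Liver coordinate and reproducibility metric

Between studies the patient moves, so VOI positions are compared in a
liver-relative frame: given a cuboid tightly circumscribing the liver, the
VOI center maps to fractions r = (center − corner)/edge per axis, and
reproducibility is the Euclidean distance between the two studies'
fractional coordinates. The reference corner is a parameter (`"min"`, the
index-minimum corner, by default; `"max"` for the opposite convention) —
distances are identical under either. Distances are reported in the
normalized unitless space; a mm-space variant is available via
`space="mm"`.

## Synthetic phantoms

The generator emulates the statistical contrast the search exploits, not
anatomy: a liver-like ellipsoid (semi-axes 75×60×50 mm, ≈1.6 L, SUV 2.5)
in soft-tissue background (SUV 1.0), a low-uptake lung ellipsoid above it
(SUV 0.5), a hot kidney-like sphere and a heterogeneous colon-like cluster
of blobs (SUV 3.5–6) abutting the liver, and optional spherical tumors.
Default grid: 168×168×108 voxels at 4.1×4.1×2.0 mm. Voxel noise is
additive Gaussian (SD 0.2 SUV) applied before a Gaussian point-spread blur
of 8.4 mm FWHM (sigma = FWHM/2.3548 per axis) standing in for scanner
resolution; Poisson count statistics and iterative-reconstruction noise
correlation are not modeled — CVv behavior only requires a homogeneity
contrast between liver and neighbors. Every voxel has exactly one label
(0 background, 1 lung, 2 liver, 3 hot organ, 10+i tumor i), and the truth
record stores nominal organ SUVs and exact tumor voxel counts.

Consequences of the blur worth knowing when reading tests: the mean SUV
over the *whole* liver label sits ~4% below nominal (boundary spill-out
against SUV-1.0/0.5 neighbors), while the liver interior — the label eroded
by the 15-mm reference-VOI radius, i.e. the region the reference VOI can
actually sample — stays within 2% of nominal. Measured MTV likewise differs
from ground truth by a partial-volume rim. Passing tests therefore show
correct behavior under idealized piecewise-constant anatomy with Gaussian
blur and noise; they do not certify performance on real heterogeneous
livers, pathological uptake, or non-Gaussian reconstruction noise.

`paired_study` builds two studies of one subject: independent noise, a
random rigid offset of all structures (magnitude ≤ 5 mm, matching typical
repositioning within the liver frame), and tumor diameters rescaled by the
cube root of the requested volume-change factor.

## Agreement statistics

ICC is fixed to the two-way, absolute-agreement, single-measure form
ICC(2,1) — flavors differ materially, so this is stated prominently; it is
computed closed-form from the ANOVA mean squares (cross-checked against
`pingouin` in tests) with a seeded percentile bootstrap CI over subjects
(2000 replicates by default). Bland-Altman limits use mean ± 2·SD of the
differences exactly (not 1.96). Holm adjustment is delegated to
`statsmodels`, the paired t-test to `scipy`. Identical-rater data is a
degenerate case reported as ICC 1 with a flag.

## Batch experiment sizes

The reproducibility experiment uses 50 phantom seeds with two placements
per seed (search center jittered uniformly within ±10 mm per axis — two
simulated operators) at 40- and 80-mm neighborhoods; 50 seeds put the
standard error of a ~95% success rate near 2% while keeping the full batch
around 20 s. Measured on this batch, the 80-mm neighborhood places the
reference VOI fully inside the liver in 100% of runs with 100% run-to-run
voxel agreement, whereas 40 mm fails in a few percent of runs (locking
onto locally homogeneous patches of the hot cluster) with a larger
inter-run liver-coordinate distance — the behavior the defaults are chosen
for.

## Known limitations

- No automatic liver segmentation or liver-cuboid derivation on clinical
  data (phantom cuboids come from ground-truth labels).
- No DICOM ingestion or SUV computation from injected dose; inputs are
  already-quantified SUV volumes.
- Thresholding applies no connected-component filtering within candidate
  regions.
- The phantom's Gaussian noise/PSF idealization above.
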
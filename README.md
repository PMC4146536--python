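# livervoi

Semi-automated placement of the PERCIST liver reference VOI on FDG PET-CT,
and threshold-based metabolic tumor volume (MTV) measurement.

## The problem

PERCIST 1.0 measures tumor burden on FDG PET relative to a liver reference:
a 30-mm spherical volume of interest (VOI) placed in the right lobe of the
liver, whose SUV mean and SD set the tumor-delineation threshold. Manual
placement of that sphere is subjective — an operator who (deliberately or
not) picks a high- or low-uptake patch of liver shifts the threshold and,
with it, every volume-based measurement downstream. `livervoi` automates the
placement so that the threshold, the MTV and its inter-study change become
operator-independent. It is aimed at physicists and physicians working with
quantitative PET response assessment, and at methodologists who need a
reproducible reference-region pipeline they can stress-test in silico.

## The algorithm

The liver is a large organ of moderately high, comparatively *homogeneous*
uptake. For a voxel v, define the coefficient of variation

    CVv(v) = SD / mean  of SUV over a sphere of diameter d centered at v.

CVv is small deep inside the liver and large near organ boundaries and
heterogeneous FDG-avid neighbors (colon, kidney). The method:

1. An operator places one large search sphere (diameter 150 mm) roughly
   over the right liver lobe — the only manual input.
2. CVv is computed at every voxel of the search sphere over a medium
   neighborhood sphere (default d = 80 mm).
3. The 30-mm reference VOI is centered on the voxel of minimum CVv; its
   mean m and sample SD s give the delineation threshold **T = m + 3 s**.
4. Within expert-agreed candidate tumor regions, every voxel with SUV > T
   is tumor; MTV is the summed voxel volume (ml), TLG = mean tumor SUV x
   MTV, and response is the relative MTV change between paired studies.

Local statistics run as FFT convolutions of the image, its square, and a
binary spherical kernel on the anisotropic voxel lattice, validated against
the brute-force per-voxel definition. Placement reproducibility is
evaluated on synthetic phantoms with ground-truth organ labels, using a
liver-relative coordinate (VOI position as fractions of a liver-bounding
cuboid's edges), two-way absolute-agreement ICC, Bland-Altman limits
(mean difference +/- 2 SD), paired t-tests and Holm-adjusted P-values.

## Worked example

```python
from livervoi import (PhantomSpec, Tumor, generate_phantom,
                      place_reference_voi, delineate)
from livervoi.phantom import TUMOR_LABEL_BASE

spec = PhantomSpec(seed=7, tumors=(Tumor((440.0, 470.0, 80.0), 40.0, 4.0),))
grid, labels, truth = generate_phantom(spec)

report = place_reference_voi(grid, voi_large_center_mm=(260.0, 280.0, 108.0))
regions = (labels.values >= TUMOR_LABEL_BASE).astype(int)
seg = delineate(grid, regions, report.threshold)
```

prints (via the report fields):

```
reference VOI center : (241.9, 282.9, 108.0) mm
VOI mean / SD        : 2.4863 / 0.0212 SUV
threshold (mean+3SD) : 2.5497 SUV
minimum CVv          : 0.0102
MTV                  : 29.69 ml (true voxel volume 33.38 ml)
TLG                  : 103.27 SUV*ml
```

The selected center sits inside the phantom's liver label; the threshold is
the reference mean plus three SDs; the measured MTV is slightly below the
33.38-ml ground truth because the 8.4-mm-FWHM point-spread blur pulls the
tumor rim below threshold (the partial-volume effect).

The same workflow is available from the shell:

```sh
livervoi phantom --seed 7 --out-dir study/
livervoi find --input study/volume.nii.gz --center 260,280,108 --out report.json
livervoi segment --input study/volume.nii.gz --regions study/labels.nii.gz \
                 --report report.json --out-json seg.json
livervoi batch --n-seeds 20 --out summary.csv
```

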
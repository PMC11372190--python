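# pvat — perivascular adipose tissue densitometry for the abdominal aorta

CT attenuation of the fat immediately surrounding a vessel rises when the
vessel wall is inflamed, which makes perivascular adipose tissue (PVAT)
density a candidate non-invasive imaging marker of vascular inflammation.
`pvat` implements this analysis for the abdominal aorta and abdominal aortic
aneurysms (AAA): starting from a contrast-CT volume in Hounsfield units (HU),
a binary aortic segmentation, and a handful of anatomic landmarks, it
computes distance-resolved fat attenuation markers per aortic section and
runs the cohort statistics needed to compare patient groups and to evaluate
automated segmentation pipelines.

It is written for imaging researchers who have segmentations (manual or from
a model such as an nnU-Net) and want a tested, reproducible measurement
stack — including synthetic CT phantoms with analytically known ground truth,
so every stage can be validated without access to patient data.

## The measurement

For each aortic section the package reports, over the adipose voxels
(−190 HU ≤ HU ≤ −30 HU) at physical distance *d* from the outer aortic wall:

- **HU_close** — mean HU for *d* ∈ [2, 5) mm,
- **HU_distant** — mean HU for *d* ∈ [10, 12) mm,
- **HU_Δ = HU_close − HU_distant** (HU) and
  **HU_ratio = 100 · HU_close / HU_distant** (%), the intra-individually
  normalised markers of near-wall fat density elevation,

with the 0–2 mm rim excluded (adventitia and partial-volume effects) and any
section whose close or distant shell holds less than 0.3 cm³ of fat flagged
invalid and excluded from comparisons. Distances are exact anisotropic
Euclidean distances in mm, not voxel-count dilations. Sections (aneurysmal,
non-aneurysmal abdominal, infrarenal) are delimited by projecting the
anatomic landmarks — aortic bifurcation, coeliac trunk, right renal artery
junction, aneurysm ends — onto a centerline extracted from the segmentation,
and every voxel inherits the section of its nearest centerline point.

Cohort statistics cover the two standard designs (two-sample t-test of AAA
aneurysmal vs control infrarenal sections; paired t-test of aneurysmal vs
non-aneurysmal sections within AAA patients) plus automation-agreement
metrics: Dice overlap, ICC(2,1) with F-based 95% CI, bootstrap CI of the
mean per-patient marker difference, and arc-length deviation of predicted
aneurysm ends.

## Worked example

```python
from pvat import (PhantomConfig, AneurysmSpec, FatProfile, generate_phantom,
                  extract_centerline, section_aorta, LandmarkSet, measure_patient)

config = PhantomConfig(
    aneurysm=AneurysmSpec(center_s_mm=30, length_mm=24, max_radius_mm=12),
    fat_profile=FatProfile(inner=-75, close=-75, gap=-80, distant=-85, outer=-85),
    noise_sigma=5.0, fat_fraction=0.9, seed=7,
)
volume, truth = generate_phantom(config)
cl = extract_centerline(truth.segmentation, volume.spacing)
sections = section_aorta(truth.segmentation, volume.spacing, cl,
                         LandmarkSet(truth.landmarks))
for m in measure_patient(volume, truth.segmentation, sections, patient_id="demo"):
    print(f"{m.section:26s} hu_close={m.hu_close:7.1f}  hu_distant={m.hu_distant:7.1f}  "
          f"hu_delta={m.hu_delta:5.1f}  hu_ratio={m.hu_ratio_pct:5.1f}%  valid={m.valid}")
```

prints

```
aneurysmal                 hu_close=  -75.1  hu_distant=  -85.0  hu_delta=  9.9  hu_ratio= 88.3%  valid=True
non_aneurysmal_abdominal   hu_close=  -75.0  hu_distant=  -85.0  hu_delta= 10.0  hu_ratio= 88.2%  valid=True
```

The phantom renders near-wall fat at −75 HU and distant fat at −85 HU; the
pipeline recovers HU_Δ ≈ 10 HU and HU_ratio ≈ 88% through segmentation,
centerline extraction, sectioning and shell measurement, despite 5 HU of
added noise and 10% non-fat admixture. A positive HU_Δ with a ratio below
100% is the signature of denser (more water-like) fat against the wall.

## Command line

```bash
pvat phantom --out cohort/ --seed 1 --n-aaa 2 --n-control 2   # synthetic cohort + manifest
pvat run --config cohort/run_config.yaml                      # full pipeline
pvat measure --volume v.nii.gz --mask m.nii.gz --landmarks lm.json --out meas.csv
pvat cohort --measurements out/measurements.csv --comparison inter --marker delta --out inter.json
pvat agree --reference ref.csv --predicted pred.csv --out agreement.json
```

`pvat run` writes per-patient measurements (CSV), group comparisons (JSON),
agreement metrics when predicted segmentations are supplied, and a run log
recording every parameter and exclusion.

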
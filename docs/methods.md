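# Methods

## Measurement model

The quantity of interest is the CT attenuation of perivascular adipose
tissue (PVAT) as a function of physical distance from the outer aortic wall.
Let `M` be the binary aortic segmentation (lumen, wall and — where present —
mural thrombus inside the outer contour; the mask's outer boundary is taken
as "the wall") and `d(x)` the Euclidean distance in mm from the center of
voxel `x` to the center of the nearest voxel of `M`, computed with the exact
anisotropic distance transform (`scipy.ndimage.distance_transform_edt` with
the voxel spacing as sampling). For a section `S` of the aorta and a
distance band `[lo, hi)` the shell mean is the voxel-pooled average

    HU_band(S) = mean { HU(x) : x ∉ M,  lo ≤ d(x) < hi,
                         −190 ≤ HU(x) ≤ −30,  section(x) = S }

with `close = [2, 5) mm` and `distant = [10, 12) mm`, and the markers

    HU_Δ     = HU_close − HU_distant          (HU)
    HU_ratio = 100 · HU_close / HU_distant    (%).

Assumptions and conventions:

- **Fat window** −190…−30 HU, both bounds inclusive (the conventional CT
  adipose range; water at 0 HU is excluded).
- **Bands half-open** `[lo, hi)`, so adjacent bands can never double-count a
  voxel. The 0–2 mm rim is excluded from every statistic (adventitia,
  partial-volume contamination, calcification blooming); the 5–10 mm gap is
  deliberately measured by neither band.
- **Distance, not dilation.** Iterated binary dilation counts voxels, so the
  shell thickness would depend on spacing and direction; the exact distance
  transform gives spacing-faithful mm shells and is checkable against
  brute-force nearest-voxel search. Distances are straight-line, not
  geodesic around other organs.
- **Validity rule.** A measurement with less than 0.3 cm³ of adipose tissue
  in either shell is flagged invalid and excluded from cohort comparisons;
  empty shells produce NaN means plus the invalid flag, never silent zeros.
  Exclusions carry a per-patient reason string through to the run log.

## Sectioning geometry

Anatomic sections are intervals of centerline arc-length. The centerline is
extracted from the segmentation as a *medial geodesic*: voxels of `M` form a
26-connected graph with physical edge lengths; a double geodesic sweep
(farthest voxel from an arbitrary seed, then farthest from that) finds the
two extremal ends; the connecting minimal-cost path, with cost per mm scaled
by `1/(depth + 0.5)²` where `depth` is the interior distance to the
background, tracks the middle of the lumen. Topological thinning was
rejected after testing: on symmetric tubes (axis between voxel centers) 3-D
thinning can erode the mask to nothing, and on bulging masks it returns
fragments. The cheapest exit from an end face is a diagonal, so end
segments with strictly increasing depth are pruned and replaced by a
tangential extension to the mask boundary; the path is then smoothed with a
5-point moving average and resampled at 1 mm arc steps. On straight
cylinders the result is the exact axis; end effects keep the recovered
length within about one local radius of truth, and on curved phantoms the
length error is below 5%.

Landmarks (aortic bifurcation, coeliac trunk, right renal artery junction,
aneurysm inferior/superior ends) are projected to the nearest centerline
point — ties resolve toward smaller arc-length — and the bifurcation anchors
arc-length zero, fixing orientation. Section membership of *every* voxel
(aortic and perivascular alike) is by the arc-length interval containing its
nearest centerline point, with the aneurysmal interval taking precedence
inside the abdominal span. Nearest-point assignment was chosen over literal
perpendicular cutting planes: the two agree on near-straight vessels, but
cutting planes can intersect inside curves, while nearest-point assignment
is always well defined and admits an exhaustive-search oracle. Deviation of
predicted aneurysm ends is likewise measured as the absolute arc-length
difference of their projections, matching the along-vessel meaning of an
"end".

## Cohort statistics

- **Inter-individual**: two-sample two-tailed t-test of a marker between AAA
  aneurysmal sections and control infrarenal sections. The classic
  equal-variance form is the default (matching the common toolkit default);
  Welch's form is available via `equal_var=False`.
- **Intra-individual**: paired two-tailed t-test between aneurysmal and
  non-aneurysmal abdominal sections within AAA patients. Pairs with zero
  within-pair variance make the statistic undefined; the result is flagged
  `degenerate: no within-pair variability` instead of being coerced.
- **Agreement**: Dice overlap `2|A∩B|/(|A|+|B|)` (defined as 1 for two empty
  masks); ICC(2,1) — two-way random effects, absolute agreement, single
  measure — via ANOVA mean squares with the McGraw–Wong F-distribution 95%
  CI (the two-way model is the defensible choice when neither model nor form
  is dictated; the implementation is cross-checked against pingouin);
  percentile bootstrap (default 1000 resamples, seeded generator) for the
  mean per-patient absolute marker difference — percentile rather than BCa,
  as the plain method is the natural reading of "bootstrap CI" and is exact
  in the degenerate constant-difference case. HU_ratio is analysed on the
  percent scale throughout. No multiplicity correction is applied across
  markers or comparisons.

## Synthetic phantoms

The phantom emulates a contrast-enhanced abdominal CT at the aorta: a
z-aligned (optionally sinusoidally curved) tube with a contrast-bright lumen
(default 300 HU), a soft-tissue wall ring (40 HU, default 2 mm), an optional
fusiform (axisymmetric cos² bulge) or saccular (one-sided, angularly
weighted bulge) aneurysm, perivascular fat with a programmable radial HU
profile per band, non-fat background tissue (30 HU), i.i.d. per-voxel
fat/background interleaving with probability `fat_fraction`, and optional
additive Gaussian noise. Defaults: 57×57×64 grid at 1×1×1 mm (odd in-plane
size puts the axis on voxel centers), lumen radius 7 mm, fat at −100 HU —
a deliberately scaled-down abdominal aorta so that a full cohort renders in
seconds; the published cohort's aneurysms average ~25 mm radius, which only
enlarges the grid without changing any measured contrast.

Two discretisation choices make the ground truth exact rather than
approximate. Vessel membership is decided per voxel center with no
anti-aliasing, and the fat *bands* are laid out with the same discrete
distance metric the measurement stage thresholds (distance to the nearest
vessel-voxel center), so `expected_shell_means` equals the configured band
value exactly under full fat fraction and zero noise — verified per voxel by
brute-force enumeration in the tests.

Cohorts draw per-patient fat attenuation from group distributions: distant
HU ~ N(μ_d, σ_d) and the close−distant contrast ~ N(μ_Δ, σ_Δ), with the AAA
arm defaulting to μ_Δ = 8.9, σ_Δ = 5.1 HU against −83.9 ± 13.5 HU distant
fat, and the control arm to 6.9 ± 4.8 HU against −83.4 ± 12.5 HU — the group
moments of the study design this package targets. Draws are clipped to the
adipose window (the clip binds only beyond ±4σ). Per-patient generators are
spawned from a single `SeedSequence`, so cohorts are bit-reproducible and
patients are independent.

What the phantom does *not* model — and hence what passing tests do not
show about real data: CT physics (beam hardening, streak artifacts, iodine
blooming, detector noise correlation), mural thrombus and calcification,
respiratory/cardiac motion, neighbouring organs inside the 12 mm
neighbourhood (in vivo, bowel or kidney can displace fat and shrink shells
far below 0.3 cm³), and anatomic variation of landmark positions. The
phantom validates the measurement geometry and statistics, not the
biological effect size.

## Numerical choices and degenerate inputs

- Fat-band HU equality at band borders is exact by construction (see above);
  all oracle comparisons in the tests therefore use tolerances at rounding
  level (1e-9) rather than physical partial-volume allowances.
- Nearest-point ties (a voxel equidistant from two centerline points)
  resolve to the smaller arc-length, deterministically, in both the
  implementation and its oracles.
- `extract_centerline` requires a single 6-connected component of at least
  50 voxels; smaller satellites are ignored, multiple large components are
  an error listing their sizes.
- Segmentations must share grid shape and spacing with the volume and have a
  diagonal affine; violations are reported by `validate_inputs` (and fatal
  in `run_pipeline`) rather than silently resampled.
- Markers are reported at full precision in `measurements.csv`; the summary
  table rounds to one decimal, the precision at which such cohort tables are
  conventionally printed.

## Problem sizes

The test suite and the acceptance script use 50-patient-per-arm phantom
cohorts on the default 57×57×64 grid, 100 random ≤27³ grids for exhaustive
oracle comparison, 100 simulations for power and 1000 for type-I
calibration — sizes at which every check runs in minutes on a single CPU
while keeping Monte-Carlo error well inside the asserted bands.

## Known limitations

- The centerline is designed for a single unbranched vessel; the aortic arch
  with branch vessels attached to the mask would need pre-trimming.
- Straight-line distance shells ignore organ boundaries; fat on the far side
  of an adjacent structure still counts if inside the window and band.
- Whether real segmentations include mural thrombus inside the wall contour
  changes what "wall distance" means; this package measures from the outer
  boundary of whatever mask it is given.
- ICC model/type conventions differ across toolkits; only ICC(2,1) is
  implemented.
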
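# Methods

## Problem and scope

`kneequant` quantifies tibiofemoral articular cartilage from labelled
(already-segmented) 3D knee MRI volumes and analyses its longitudinal change
in small before/after treatment trials. Segmentation itself is out of scope:
the input is an integer label volume (background, femur bone, femoral
cartilage, tibia bone, tibial cartilage) with physical voxel spacing,
typically 0.31 × 0.31 mm in-plane and 0.36 mm partitions. Two region metrics
are produced per knee:

* **projected cartilage area ratio at threshold τ** — the fraction of a
  region of interest (ROI) on the planar projection of the joint surface
  whose cartilage thickness is ≥ τ (default τ = 1.5 mm, comparison
  inclusive); and
* **mean regional thickness** — the mean projected thickness over all ROI
  pixels, with cartilage-free pixels counted as 0 mm, so full-thickness loss
  lowers the mean instead of silently shrinking the denominator.

## Quantification chain

**Canonical frame.** Axis 0 runs anterior→posterior, axis 1 medial→lateral
(right-knee orientation), axis 2 superior→inferior (the joint's long axis).
Left knees are mirrored along axis 1 into this frame and the mirroring is
recorded in the alignment provenance, so region names ("medial", "lateral")
are anatomically correct for both sides.

**Alignment.** The bone's long axis is the largest-spread principal axis of
its voxel positions (in mm); if it deviates from the projection direction by
more than 1°, the volume is rotated (nearest-neighbour resampling, which
preserves label integrity). A principal-spread ratio below 1.05 means the
long axis is ill-defined and raises an error. In-plane rotation then makes
the **posterior condylar line** horizontal: the chord through the most
posterior point of the medial and of the lateral half of the projected bone
footprint. Because single extreme pixels are quantized to the 0.31 mm grid
(≈1–2° of angular noise over a condylar baseline), each endpoint is
estimated sub-pixel as the mean of posterior-boundary pixels within a
1.5 mm cap of the half's extreme; the cap offset is common to both halves
and cancels in the chord angle. The discrete extreme pixel (ties broken
toward the periphery) is what the provenance records. Iteration stops when
the residual angle is below 0.5°.

**Thickness.** At each cartilage voxel, thickness = (Euclidean distance to
the nearest bone voxel) + (Euclidean distance to the nearest exterior voxel,
i.e. neither cartilage nor bone), both with anisotropic spacing
(`scipy.ndimage.distance_transform_edt`). On a flat slab of n voxel layers
this evaluates to (n+1)·dz everywhere in the interior — centre-to-centre
distances overshoot each interface by half a voxel — so it equals the
physical slab thickness to within one voxel spacing, and it degrades
gracefully on curved shells because both distances follow the local surface
normal.

**Projection.** Orthographic along the long axis; each projection pixel
keeps the *maximum* thickness among cartilage voxels on its ray (an explicit
no-cartilage marker if none) and flags whether the ray meets bone. The femur
is viewed from distal and the tibia from proximal; both maps are stored in
the volume's in-plane frame with the view direction recorded — flipping one
view is a display choice, and keeping a single frame keeps "medial" on the
same side of both maps.

**ROIs.** The femoral ROI is the filled outline of the projected bone
footprint (one closed curve; more than one connected component is an error),
cut into four quadrants by the anterior–posterior and medial–lateral
midlines of its bounding box. Bounding-box midlines rather than equal-area
splits are deliberate: equal-area boundaries would migrate as cartilage is
lost, corrupting longitudinal comparisons. The four quadrant masks exactly
partition the closed-curve interior (tested as an identity, not a
tolerance). The tibial footprint is split at its medial–lateral bounding-box
midline into medial and lateral plateau ROIs; an empty half is an error.
Only the posterior femoral quadrants and the two tibial plateaus enter the
trial analysis; the anterior quadrants are computed but excluded by
convention (they sit under the patella).

**Rendering.** Thickness above 2.0 mm renders white, 0→2.0 mm ramps
linearly red→white, cartilage-free pixels render gray (also the bone
colour); ROI outlines are overlaid. The three anchor colours are bit-exact.

**Dice.** 2·|A∩B|/(|A|+|B|) for segmentation agreement, defined as 1.0 for
two empty masks.

## Trial statistics

**Alterations.** For each patient/region/metric, `before` = value(−1 w) −
value(−30 w) and `after` = value(30 w) − value(−1 w). Patients missing a
required timepoint are surfaced as explicit problem records, never silently
dropped.

**Exact Wilcoxon signed-rank.** Differences are rounded (10 decimals)
before ranking — raw float subtraction of 2-decimal data breaks genuine ties
at the 1e-17 level and silently changes midranks. Zero differences are
dropped (`n_used` counts the rest), tied |d| receive midranks, and the exact
null is the uniform distribution over all 2^n_used sign assignments of the
observed rank multiset, walked by dynamic programming on doubled (integer)
ranks. The one-sided p is the smaller-tail probability
P(W ≤ min(W₊, W₋)); the two-sided p doubles it (capped at 1). Enumeration
is exact for n_used ≤ 20; beyond that a tie-corrected normal approximation
with continuity correction is used and flagged in the result. Reported
p-values for the packaged trial table use the one-sided value, which is what
that report printed; *significance flags* (the star convention of the
clinical-score tables) use the two-sided value, because rejecting on the
undoubled smaller-tail statistic at level α has size ≈ 2α and would not
control the type-I error the property suite checks.

**Summaries.** Median by midpoint of order statistics; quartiles by the
(n+1)·p interpolation (Hyndman–Fan type 6, `numpy` method "weibull"), which
is the convention that reproduces the packaged table's printed quartiles
(e.g. Q1 = −0.125 printed as −0.12 under half-to-even rounding). Report
rounding is half-to-even at the printed precision (2 decimals for metrics,
3 for p). Medians of 2-decimal columns that land exactly on a half-cent are
rounding-direction ambiguous against a report computed from unrounded source
data; the regression test tolerates exactly those cases.

**Screening.** A patient is eligible when the posteromedial area ratio
decreased by at least 0.03 (absolute, in ratio units, boundary inclusive)
between the −30 w and −15 w scans.

**Repeatability.** Mean absolute difference of duplicate-scan metric pairs
with a t-based 95% CI.

**Extrapolation.** Linear scaling of a per-window change to a longer
horizon (e.g. a 30-week median thickness loss of 0.15 mm extrapolates to
0.52 mm over 104 weeks).

No multiple-testing correction is applied, matching the analysis style of
the trials this mirrors.

## Synthetic phantoms and what they do (not) show

The generator builds stylised knees: two overlapping discs of radius
`condyle_radius_mm` (centres 1.1 radii apart) for the femoral condyles, a
rectangle for the tibial plateau, each bone with a narrow shaft so its
principal axis is genuinely the long axis. Articular interfaces are flat
planes normal to the projection axis: with cartilage laid down in voxel
columns, the distance-transform thickness of an n-voxel column is exactly
(n+1)·dz, so the generator fills n = round(t/dz) − 1 voxels to realise a
requested thickness t within half a voxel — the ground truth is closed-form.
The condylar/plateau *shape* lives in the footprint, which is all the
projection and ROI operators consume. Default grid (128, 128, 200) at
(0.31, 0.31, 0.36) mm, cropped around the joint; the test suite uses
(64, 64, 160) with proportionally smaller condyles for speed.

**Lesions** thin cartilage columns inside a disc of radius r₀ + growth·weeks
to a residual thickness (default 1.0 mm, i.e. below the 1.5 mm threshold but
not full-thickness loss), keeping voxels adjacent to bone. **Cohorts** draw
per-patient lesion centres, radii and growth rates from
`numpy.random.SeedSequence` substreams of one global seed, so regeneration
is reproducible patient by patient. A treatment that arrests progression is
modelled by stopping lesion growth at the last pre-treatment scan (−1 w):
stopping at the injection itself (week 0) would leave one week of growth
*between* the −1 w and 30 w scans, and the signed-rank test — blind to
magnitude — would flag that small but consistent change, which is not the
no-change-between-scans condition being emulated. **Scan noise** jitters
each cartilage column's outer boundary by round(N(0, sd)/dz) voxels
independently per scan, emulating repositioning error between duplicate
scans. **Clinical scores** (Lysholm-, KOOS- and NRS-like instruments with
their 0–100 / 0–10 bounds and directions) fluctuate around a stable
per-patient baseline and shift by a configurable effect strictly after the
onset visit (scores at the onset visit are taken pre-treatment), rounded to
instrument resolution and clipped to range.

What passing tests show: the measurement operators are exact on geometry
whose truth is known in closed form, invariant to rigid motion and
mirroring, and consistent with an independent 2D recomputation from raw
voxel columns. What they do not show: performance on real segmentations with
curved, partial-volume boundaries, segmentation errors, or anatomy-dependent
ROI placement — no MRI signal is simulated and label noise is the only
imaging artefact modelled.

## Numerical choices and limitations

* Tolerances: posterior-line horizontality 0.5°; long-axis trigger 1°;
  principal-spread degeneracy ratio 1.05; thickness fidelity one voxel
  spacing; truth-consistency of ratios 0.02.
* Nearest-neighbour resampling only (labels are categorical); each in-plane
  alignment applies a single accumulated rotation to the original grid
  rather than compounding resamplings.
* Ties in the posterior extreme pixel break toward the peripheral column;
  quadrant splits use half-open pixel ranges, so the partition identity is
  exact.
* Degenerate inputs raise typed errors (`SizingError`, `AlignmentError`,
  `ROIError`, `FormatError`) naming the offending dimension or field.
* The NIfTI sidecar JSON carries the label legend, knee side and per-scan
  metadata; spacing round-trips at float32 header precision.
* Problem sizes in the shipped tests (64×64×160 phantoms, 8-patient
  cohorts, 500 null score cohorts) were chosen to keep the whole suite
  around half a minute on one CPU while leaving every tolerance untouched.
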
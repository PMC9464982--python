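# Methods

## Scope and data model

`rtcurate` operates on the object schema of a *curated radiotherapy
dataset*: one patient directory holding a planning CT series, a curated and
a clinical RT structure set, an RT plan (photon `RTPLAN` or ion
`RTIONPLAN`), an RT dose grid, and optionally a small-field-of-view (SFOV)
CT reconstruction, a post-contrast CT and the DICOM Spatial Registration
(`REG`) object linking it. Five of these roles are required; three are
optional.

All geometry lives in the DICOM patient coordinate system (LPS: +x
patient-left, +y posterior, +z superior), in millimetres, with head-first
supine orientation assumed. Structures are stacks of closed planar contours
drawn on axial CT slices. Oblique contour planes are rejected rather than
resampled: the supported inputs are axial planning CTs, and silently
resampling a mis-oriented structure set would mask a data problem the QA
step exists to find.

## Rasterization

Every check and metric operates on the rasterization of a structure onto
the CT voxel lattice. A voxel is set iff its centre lies inside the
even-odd union of the polygons assigned to its slice; multiple polygons on
one slice combine by XOR, so an outer ring plus an inner ring produces a
"doughnut" with a hole — the convention planning systems use when
exporting RT structure sets. A contour is assigned to the nearest slice
plane when the distance is at most half the slice spacing (the native
clinical tolerance is not standardized; half a slice is the natural choice
for contours drawn *on* CT slices). Voxels are half-open boxes centred on
lattice points; volumes are `count x voxel volume` with no partial-volume
weighting, because every downstream use is a threshold comparison, not
dosimetry.

The point-in-polygon primitive is `matplotlib.path`; the test suite checks
the full rasterizer against an independently written even-odd ray-casting
oracle on randomized polygons, and checks that in-plane area error shrinks
as the lattice is refined (2 → 1 → 0.5 mm).

## The five contour checks

Per labelled structure the QA report carries PASS / FAIL / N/A for:

1. **empty** — no 2-D contours, or contours that rasterize to zero voxels
   (slivers below voxel sampling).
2. **outside_body** — any voxel outside the rasterized `body`/`external`
   outline. This check has *no* volume threshold: a single protruding voxel
   fails. N/A when no body structure exists.
3. **holes** — per-slice interior cavities (filled slice minus slice),
   grouped into 3-D 26-connected components; FAIL when any component's
   volume is ≥ the threshold.
4. **multiple_parts** — 3-D 26-connected components of the structure
   itself; FAIL when two or more components each reach the threshold.
   Sub-threshold islands ("ditzels", typically stray mouse clicks or
   format-conversion artifacts) are listed as warnings without failing.
5. **sidedness** — for `_l`/`_r` labels, the mask centroid must lie on the
   labelled side of the anatomical midline. The midline x is the mean of
   the x-centroids of the available midline organs (brainstem, spinal
   cord); with +x = patient-left, centroid x greater than the midline means
   the structure sits on the patient's left. N/A for non-lateral labels,
   empty masks, or when no midline organ exists.

The volume threshold defaults to **0.003 cc** and the comparison is `≥`
(a component exactly at threshold is flagged — the conservative reading).
Connectivity is 3-D so anatomically contiguous multi-slice organs are not
split spuriously; the per-slice 2-D part count is still reported in the
detail text. Known benign failure modes (airway holes in lungs,
naturally multi-part mastoid air cells or brachial plexus) are reported,
not suppressed: waiving them is a review decision, and an allow-list
belongs in the reviewer's hands, not the tool's.

## Overlap metrics

Standard Dice: `DSC = 2|A∩B| / (|A|+|B|)` over voxels. **Overlap DSC**
restricts both masks to the CT slices where *each* has at least one voxel
before computing the same ratio, removing the penalty for differing
superior-inferior extent and isolating in-slice agreement. "Slice has a
contour" is operationalized as rasterized occupancy (≥ 1 voxel), not the
presence of a contour item in the file — a contour that rasterizes to
nothing should not count as coverage. Undefined cases (both masks empty;
no shared slice) return `None`, never 0: conflating "no data" with "no
overlap" would corrupt cohort medians. It follows that
`overlap_dsc ≥ dsc` whenever both are defined, since intersection voxels
only live on shared slices while the restriction can only shrink the
denominator.

Cohort summaries report per-label counts alongside medians and quartiles,
because clinical structure sets frequently lack organs the curated
standard requires and the per-organ n varies.

## Completeness validation

Three passes: (1) presence of each role against the required/optional
schema; (2) linkage — the SFOV CT must share the planning CT's
Frame-of-Reference, a contrast CT must either share it or be tied to it by
a REG object, and both structure sets must reference the planning CT's
frame and series; (3) voxel constraints — planning/contrast CT in-plane
1.27 mm (1 % relative tolerance for scanner metadata rounding) with z ≤
2.5 mm and uniform slice spacing, SFOV in-plane ≤ 0.59 mm, dose grid ≤
3.0 mm per axis. "Non-standard slice spacing" is operationalized as
non-uniform inter-slice gaps (spread > 1 % of the mean gap) or z > 2.5 mm.

## De-identification

Four requirements drive the design: policy-driven tag handling,
customization, UID transformational reproducibility, and traceability.

* The **policy** is a tabular config mapping DICOM attributes to
  remove / replace / redact (regex masking) / keep. The shipped default is
  a reasonable baseline and must be reviewed against institutional and
  regulatory requirements before any use on real patient data.
* The **UID store** is a single JSON file with write-through persistence.
  Every attribute with VR `UI` — including referenced SOP instances,
  series, and Frames-of-Reference inside sequences — is remapped through
  it, except standard DICOM UIDs under the `1.2.840.10008` root. Generated
  UIDs are random-suffixed under a configurable organizational root and
  recorded, giving reproducibility by persistence rather than by keyed
  hashing (hashing would imply an irreversibility claim the design does
  not need, and the trace requirement wants reversibility anyway).
* **MRNs** map to sequential zero-padded `DEID-nnnnnn` identifiers,
  queryable singly or in batch. Dates are shifted by a stored random
  per-patient offset (uniform in −364…−7 days), preserving intervals
  between study events.
* Pixel data, contour coordinates and dose arrays are never touched.
  Re-running on already de-identified output is refused (the store tracks
  its own outputs) to avoid double-mapping ambiguity.
* `verify_integrity` re-checks the output: no policy-removed attribute
  survives, every internal reference resolves within the dataset, and
  referenced Frames-of-Reference belong to the dataset's own set.

Pixel-level scrubbing (burned-in text, face removal) is out of scope.

## The synthetic phantom

The phantom emulates the curated-dataset schema with known geometry: a
planning CT on the nominal 1.27 × 1.27 × 2.0 mm grid (96 × 96 × 40 voxels
by default), a circular body outline, the full 42-organ registry as small
ellipsoids (64-vertex circle cross-sections, so areas and volumes have
closed forms), a long-cylinder spinal cord, and plan/dose/REG stubs.
Midline organs sit on x = 0; bilateral pairs mirror about the sagittal
midplane at x = ±28 mm with the `_l` member at positive x. CT pixel
content is schematic (soft tissue inside the body ellipse, air outside,
light integer noise): no QA step reads intensities, so anatomical or HU
realism would add cost without adding test power.

A second stock configuration uses an SFOV-like 0.59 × 0.59 × 1.0 mm grid.
This exists because on the planning grid a single voxel is already
0.0032 cc — above the 0.003 cc threshold — so sub-threshold islands and
cavities can only be constructed on a finer lattice.

Defect injection edits the curated RTSTRUCT in place on a copy, so UIDs
and untouched structures are preserved byte-for-byte and exactly the
intended detector flips. Island and cavity defects are snapped to the
voxel lattice as compact staircase polygons covering exactly
`round(volume / voxel volume)` centres, with 0.45-spacing margins so no
centre sits on a polygon edge; the achieved volume is therefore exact up
to voxel quantization of the request. Generation and injection are
deterministic given the seed (sequential UIDs under a phantom root, fixed
study date, seeded noise).

What passing phantom tests do **not** show: robustness to real scanner
metadata variety, oblique or non-uniform acquisitions, interpolated or
mismatched contour planes, clinical label chaos beyond simple case
variation, or the statistical behaviour of DSC on real anatomy. The
phantom validates the machinery's contracts, not clinical performance.

## Effort statistics

Cohort effort summaries pool with sample-size weights; the pooled standard
deviation uses the population (1/n) convention,
`sqrt(Σ nᵢ(sdᵢ² + meanᵢ²)/N − mean²)`, which is exactly the sd of the
concatenated raw samples (property-tested against simulated logs). Total
per-case effort across independent workflow stages is the sum of stage
medians with stage sds added in quadrature. Display rounding is half-up to
one decimal. The packaged reference table records the per-cohort
carotid-segmentation (minutes), other-OAR segmentation (hours) and
physician review (hours) summaries for the four curation cohorts
(251 + 105 + 99 + 35 cases).

## Problem sizes and determinism

The default test and acceptance runs use the 96 × 96 × 40 planning-grid
phantom (43 structures), the 96 × 96 × 24 fine phantom, 200-instance
randomized oracle comparisons on ≤ 24³ lattices and 1000 randomized mask
pairs on a 10 × 10 × 6 grid — sizes at which every geometric property
under test is already exercised while the full suite stays fast. All
randomness is seeded; phantoms are bit-reproducible per seed.
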
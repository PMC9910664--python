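# Methods

## The segmentation model and its assumptions

The automated task list is a fixed sequence of binary image operations on
an 8-bit reconstructed volume. Its central assumptions:

- **Intensity ordering.** Air (inside and outside the animal) lies at or
  below intensity 55; soft tissue, vessels, lesions and heart lie at or
  above it. Both printed threshold ranges (55–255 for body/tissue, 0–55
  for air) are inclusive, so intensity 55 belongs to both; the two masks
  are used in different branches and never subtracted from one another.
  The final air and tissue ROIs are made disjoint by removing their
  (logged) overlap from the tissue ROI.
- **One connected air space.** The aerated lung is the largest connected
  air component inside the body; this presumes the lungs communicate
  through the conducting airways and are not severed by consolidation.
- **Closing reaches every intra-lung structure.** The per-slice round
  closing of radius 40 px must span vessels and lesions (it fills holes up
  to its radius) without bridging the mediastinum — valid when the
  inter-lung distance exceeds twice the radius in pixel units. At coarse
  fields of view where the lungs come within 2×radius of each other, the
  closing bridges them and the tissue ROI acquires mediastinal tissue;
  that is a property of the method, not of this implementation.
- **Erosion trades rim for specificity.** The radius-1 per-slice erosion
  of the tissue selection removes the chest-wall rim the closing pulled
  in, at the documented cost of a one-pixel shell of every true tissue
  structure (a warning is logged on every run).

16-bit input is accepted; thresholds are never rescaled (a warning is
logged), because silent rescaling corrupts reproducibility.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| body/tissue threshold | (55, 255) | intensity | published task-list value for 8-bit reconstructions |
| air threshold | (0, 55) | intensity | ditto; shares 55 with the tissue range by design |
| shrink-wrap diameter | 4 | px | widest body-surface opening to bridge |
| closing radius | 40 | px | fills intra-lung holes (vessels/lesions) in-slice |
| erosion radius | 1 | px | strips peripheral tissue rim |
| voxel size | 35 (in vivo), 9 (ex vivo) | µm | scanner classes the method targets |

All operator radii are in pixels, as in the vendor software; their
physical meaning therefore changes with voxel size.

## Fixed numerical conventions

- **Connectivity**: 26 (3D) / 8 (2D) for foreground, complementary 6 / 4
  for background — the standard duality that keeps hole filling
  paradox-free.
- **Round element**: pixel centres within Euclidean distance ≤ radius.
  Round-element erosion/dilation are computed exactly via the Euclidean
  distance transform.
- **Border contract**: dilation pads beyond the volume border with
  background, erosion with foreground, so closing never trims objects at
  the border. Consequence: a closing whose dilation clips at the border
  bulges to the volume edge (objects should stay more than one closing
  radius away from the border; the phantom does).
- **Despeckle ties**: among equal-sized components the one whose first
  voxel in (z, y, x) raster order comes first is kept — deterministic and
  order-independent.
- **Shrink-wrap**: per slice, close with radius ⌈diameter/2⌉, flood-fill
  the background from the border (4-connectivity), take the complement,
  and intersect with the dilated filled convex hull of the original
  foreground. The hull guard interprets the "filled hull" bound as the
  convex hull; since a closing is always contained in the convex hull, the
  guard is a safety net and never trims the wrap. The vendor operation's
  internals are proprietary; this definition is a declared contract, not
  claimed bit-compatibility.
- **Structure thickness**: local thickness by distance-ridge sphere
  painting. A foreground voxel at EDT distance d holds an inscribed
  sphere of diameter 2d − 1 voxels covering voxels within d − 0.5 of it;
  radii are quantised to the nearest integer and painted largest-first
  (one EDT per distinct radius over the foreground bounding box). The
  distance map is computed on the full array, never on a crop, so masks
  that fill their bounding box keep correct distances. The array border
  does not count as background (a slab spanning the volume reads its true
  thickness); a mask that fills the entire volume falls back to
  border-as-background. Single voxel → thickness 1; 10-voxel slab → 9
  (within the 1-voxel quantisation of the convention).
- **Structure linear density**: directed secants along the three axes,
  one test line per voxel row/column/pillar (a stride option subsamples
  for very large volumes); runs break where a line leaves the VOI; axis
  value = runs / in-VOI line length. In the pipeline the tissue VOI is the
  tissue ROI itself, so the statistic is the reciprocal mean chord length
  of the tissue — it decreases as structures coalesce. Because vendor
  software does not document its formula, the plate-model alternative
  (BV/TV)/St.Th is reported side by side; neither is claimed to match
  vendor magnitudes.
- **Meshes**: scikit-image's Lewiner marching cubes (the topologically
  consistent variant) on the zero-padded binary mask at level 0.5,
  vertices in mm, faces oriented so the divergence-theorem volume is
  positive; zero-area faces dropped at construction.
- **Degenerate inputs**: empty masks raise (despeckle "no objects",
  shrink-wrap "nothing to wrap", thickness/meshing on empty or all-true
  masks); two empty masks compare with Dice 1 (logged); a uniform volume
  fails segmentation with "no lung air"; an aerated volume below 1 mm³
  logs an implausibility warning.

## The synthetic thorax: what it emulates and what it does not

The generator builds a stated world for validation, not a simulator:
an ellipsoidal soft-tissue body (intensity 120) in air (20); two lung
fields of parenchyma (35) whose voxelwise truth is the air mask; a
conducting airway (trachea, mainstem bronchi entering at the apices) that
makes the two lungs one connected air space; one bifurcating vessel tree
per lung (130) restricted to the three arterial generations resolvable at
35 µm (trunk radius 11 px ≈ 0.39 mm, floor 5 px ≈ 175 µm), oriented
craniocaudally like the bronchovascular bundles; bronchocentric lesions
(110) grown as spherical blobs around six fixed foci in the lung core so
that a rising lesion fraction coalesces lesions — at a fixed seed, lesion
masks are nested across fractions and the noise field is identical; a
ventral-medial heart (125); additive Gaussian noise (sd 6, clamped to
0–255). Intensities sit ≥ 15 units clear of the 55 threshold so tests
probe the pipeline, not threshold luck.

Geometric constraints at the default 200×256×256 field of view: the chest
wall encloses the lungs in every slice (otherwise the shrink-wrap flood
fill leaks into the lung field); the mediastinal gap exceeds 2×40 px
(no closing bridge); the lungs stay > 40 px from the volume border
(no border bulge under the erosion border contract).

Not emulated — and therefore not established by a green test: partial
volume effects, beam hardening, ring and motion artifacts, anisotropic
noise, subpleural/peripheral consolidation (which the task list is
documented to lose and which calls for the manual pre-ROI fallback),
vessels below in-plane resolution, respiratory gating. Dice scores on the
phantom bound what the pipeline's operators do under the stated intensity
model; they do not certify scanner data.

The dried-lung phantom for the ex vivo path is a single lobe (tissue with
air pockets and an embedded finer vessel tree, on an air background, 9 µm
class): the ex vivo task list keeps one connected component, and a
two-lobe specimen without a connecting hilum would lose a lobe. All
phantoms are synthetic stand-ins and say so in their provenance strings.

## Design choices where the design was open

- The "erosion … apply to image" step erodes the binary tissue selection
  (per slice) before the final ROI intersection — matching the stated
  purpose of eroding peripheral tissue; the intra-lung tissue cost is
  logged.
- The optional second despeckle and the manual-modification ROI export
  exist behind flags, both off by default.
- A failed step aborts the run with its step index rather than being
  skipped: silent partial segmentations are the main manual-QC hazard.
- Task lists are plain text, one step per line (`name key=value …`),
  round-trip stable; the shipped default file has the 20 operational
  steps of the published sequence with the two optional steps disabled.
- The CLI exit codes are fixed (0 ok, 1 usage/I-O, 2 analysis failure)
  for pipeline embedding, and overlay QC images (ROI tinted red over the
  grayscale) are always written, mirroring recommended practice of
  checking the automated ROI by eye.

## Known limitations

- Operator definitions (shrink-wrap, despeckle) are declared contracts;
  bit-compatibility with closed vendor implementations is neither claimed
  nor testable.
- Published in vivo aerated-lung volumes for mice (hundreds of mm³) come
  from full-field scans; the desk-scale phantom is a miniature (tens of
  mm³), so absolute volumes are not comparable to animal data — only the
  method's behaviour is.
- The radius-40 closing is quadratic in relative scale: at small fields
  of view it bridges the mediastinum (see assumptions), which is why the
  full-size phantom is used for accuracy criteria and small phantoms only
  for smoke/property tests.
- St.Li.Dn magnitudes depend on the VOI convention (full volume for
  calibration phantoms, the ROI itself in the pipeline); values are
  comparable within a convention only.
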
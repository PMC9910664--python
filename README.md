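# pats-microct

Automated **P**ulmonary **A**ir and **T**issue **S**egmentation (PATS) and 3D
morphometry for mouse thoracic microCT, as an open, scriptable Python
package.

## The problem

Quantifying lung disease in small-animal microCT means separating three
compartments in a reconstructed grayscale volume: the air-filled (aerated)
lung, the intra-lung tissue (vessels plus dense, diseased or inflamed
tissue), and everything else (chest wall, heart, diaphragm). Manual ROI
drawing takes an expert about an hour per mouse and is the main source of
inter-observer variability; vendor analysis software can run an automated
"task list" that does the same job in minutes, but such task lists live
inside closed GUIs. This package re-implements that automated task list
with fully specified operator semantics, so the same segmentation can be
scripted, version-controlled and validated.

Intended users: preclinical pulmonary researchers (fibrosis, acute lung
injury, silicosis models) and image-analysis engineers who need a
reproducible, headless segmentation step in a pipeline.

## The method

The task list operates on an 8-bit slice stack with a state of three
layers — the original image, the current ROI, and a binary selection:

1. **Body**: global threshold 55–255 segments the animal from surrounding
   air; a per-slice **shrink-wrap** (bridging surface openings ≤ 4 px)
   turns it into a solid body ROI.
2. **Aerated lung**: reload, threshold 0–55 inside the body ROI
   (ROI = air within the body), then a 3D **sweep despeckle** keeps the
   single largest connected air component — the lungs plus conducting
   airways. Basic 3D analysis and an STL surface model are produced.
3. **Lung tissue**: a per-slice round **closing** of radius 40 fills
   vessels and lesions, converting the aerated ROI into a whole-lung ROI;
   after reload, threshold 55–255 inside it selects tissue, and one
   per-slice round **erosion** of radius 1 strips the rim of peripheral
   tissue the closing pulled in. The result is the vessels-and-dense-tissue
   ROI, analysed with basic plus additional values and meshed.

Morphometry follows standard microCT nomenclature: TV (VOI volume), BV
(object volume), BV/TV, **St.Th** (structure thickness — volume-weighted
mean diameter of the largest inscribed spheres, by distance-transform
sphere painting) and **St.Li.Dn** (structure linear density — directed
secants: foreground runs per unit test-line length, per axis; a
plate-model alternative (BV/TV)/St.Th is reported alongside). Surfaces use
topologically consistent marching cubes and are written as STL.

Because no public scan data accompany the method, the package ships a
synthetic thorax phantom generator (body, two lung fields, conducting
airway, vessel trees, coalescing lesions, heart, calibrated noise) with
voxel-level ground truth, plus analytic calibration phantoms (sphere, slab
stack, rod grid, dried lung) — the whole pipeline is testable with no
scanner.

## Worked example

```python
import pats

# the default synthetic thorax: 200x256x256 at 35 um, seed 42,
# 20 % lesion volume fraction, Gaussian noise sd 6
truth = pats.generate_thorax_phantom(pats.PhantomSpec())
result = pats.pats_segment(truth.volume)

m = result.tissue_morphometry
print("aerated volume:", result.aerated_morphometry.object_volume_mm3)
print("tissue volume:", m.object_volume_mm3)
print("tissue St.Th:", m.structure_thickness_mm)
print("tissue St.Li.Dn:", m.structure_linear_density_per_mm)
print("air Dice:", pats.compare_rois(result.aerated_roi,
                                     truth.masks["lung_air"]).dice)
```

prints (up to float formatting):

```
aerated volume: 14.358 mm^3
tissue volume: 5.453 mm^3
tissue St.Th: 0.635 mm
tissue St.Li.Dn: 1.605 /mm
air Dice: 0.9999
```

The aerated volume is the air inside the lungs and airways; the tissue
volume is the vessels-and-dense-tissue compartment inside the closed lung
ROI (at 20 % lesion burden it is dominated by lesions); St.Th is the mean
structure calibre and St.Li.Dn the number of tissue structures crossed per
millimetre of test line — it falls as lesions coalesce, which is how
consolidation reads in this statistic. The Dice score is the overlap with
the phantom's ground-truth air mask.

The same run from a shell, with overlay QC images and CSV/STL outputs:

```bash
pats phantom thorax --seed 42 --out phantom/
pats segment phantom/volume --out results/ --pattern '*.bmp'
pats compare results/aerated_lung phantom/truth_lung_air
```

## Acceptance script

`scripts/acceptance.py` regenerates the default phantom from its seed,
runs the full segmentation, quantifies both compartments against the
phantom ground truth, prints the summary, and writes the results JSON:

```bash
python scripts/acceptance.py --seed 42 --out results/acceptance.json
```

## Layout

- `pats.io_volumes` — slice stacks (BMP/TIFF/PNG), dataset logs, ROI
  stacks, STL meshes, CSV reports
- `pats.core_ops` — thresholding, bitwise ops, despeckle, morphology,
  shrink-wrap
- `pats.pipeline` — the task-list engine, the shipped 20-step default
  list, `pats_segment`, `ex_vivo_segment`
- `pats.morphometry` — volumes, St.Th, St.Li.Dn, meshes, ROI comparison
- `pats.phantom` — synthetic thorax and calibration phantoms with truth
- `pats.cli` — the `pats` command (segment / exvivo / phantom / compare /
  mesh)

See `docs/methods.md` for the model assumptions, parameter defaults, the
phantom's design and its limits, and numerical conventions.
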
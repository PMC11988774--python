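# Methods

## Problem setting

A bitewing radiograph (BR) captures the crowns of upper and lower posterior
teeth of one side of the mouth. Proximal caries — lesions on the mesial
(toward the dental midline) or distal (away from it) contact surfaces — are
graded radiographically by ICCMS™ stage: RA (initial), RB (moderate),
RC (extensive). Given two independent detector outputs per image — caries
instances (polygon outline + bounding box + severity + confidence) and
FDI-numbered tooth bounding boxes — the package assigns each lesion to an
affected tooth and surface and scores detector output against reference
annotations. Both detectors are treated as black boxes; only their boxes,
outlines and scores enter the computation.

## Coordinate and geometry conventions

Continuous pixel coordinates, origin top-left, x rightward, y downward.
Boxes are closed real intervals stored in corner form; YOLO center-form
appears only at file I/O. A `CariesDetection`'s box must equal its
polygon's tight bounds within 1e-6 px — this is enforced at construction,
so boxes can never drift from their outlines.

Mask IoU rasterizes polygons with a pixel-center rule: pixel (i, j) belongs
to a mask iff the point (i+0.5, j+0.5) lies inside or on the polygon. This
makes mask IoU bit-reproducible and, for axis-aligned rectangles, keeps it
within a couple of boundary pixels of the exact box IoU (a property test
asserts agreement within 0.08 absolute on ≥200×200 frames).

## Tooth assignment

For each lesion, the tooth boxes intersecting its bounding box (area
strictly above `min_overlap_area`, default 0) are collected and sorted by
descending intersection area, ties by ascending FDI. Three scenarios:

1. **One intersecting tooth** → that tooth.
2. **Several, with a strict area maximum** → the argmax. "Degree of
   overlap" is raw intersection area, not IoU: IoU would penalize large
   tooth boxes, which is wrong for a small lesion.
3. **Complete coverage by ≥2 teeth, or exactly tied areas** → the tooth
   whose nearest *vertical* box edge is horizontally closest to the
   lesion's box center (proximal surfaces are vertical in bitewing
   orientation); remaining ties go to the ascending FDI. "Complete
   coverage" means overlap ≥ (1 − tol)·lesion-box area with tol = 1e-6 —
   exact containment is numerically fragile. The rule generalizes to more
   than two covering teeth.

No intersecting tooth at all yields an *undetermined* diagnosis (a value,
not an error); this is exactly what happens when the numbering model misses
a tooth cut off at the image border.

Masks are deliberately ignored here: assignment consumes boxes only, so it
works identically for segmentation and plain detection front ends.

## Surface rule and the side convention

The affected surface compares the lesion box x-midpoint `cx` with the
assigned tooth's x-midpoint `tx`, given the BR side. The package's
convention (`MESIAL_X_SIGN`): on a right-side BR the midline lies toward
+x, on a left-side BR toward −x; the lesion is mesial iff `cx − tx` points
toward the midline. Which image direction is mesial for each side is a
display convention the data itself does not pin down; the choice is
isolated in one constant so the mirrored convention is a one-line change,
and the synthetic generator lays out FDI numbers consistently with it,
which makes the horizontal-flip consistency property exact (flipping a
scene toggles the side and leaves every diagnosis unchanged).

`|cx − tx| ≤ 1e-9` or an unknown side (not inferable from the teeth's FDI
quadrants by majority vote) gives an undetermined surface.

## Evaluation protocol

Predictions below the confidence threshold are dropped; survivors are
processed in descending confidence and greedily matched, class-exclusively,
to the unmatched same-class ground truth of highest IoU; a match is a TP
iff IoU ≥ the IoU threshold, otherwise FP; unmatched ground truths are FN.
Precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their harmonic mean, with
0/0 → 0 so empty edge cases are total. A small-instance property test
checks the greedy matcher attains the exhaustive maximum matching whenever
IoUs are cleanly bimodal (≥ threshold or 0), the regime the generator
produces.

AP is computed at confidence threshold 0 with all-point interpolation
(monotone non-increasing precision envelope); detections are pooled over
all images with a single global confidence ranking (per-image averaging is
an alternative some tools use; joint pooling is the standard choice here).
Macro precision/recall/F1 are unweighted class means and
mAP = (1/C)·Σ APᵢ; the macro means are what reproduce a published
per-class/overall metric table's overall row, which support-weighted means
do not. Classes with zero ground-truth instances have undefined AP and are
excluded from the macro mean with a warning. Box IoU suits
object-detection output and mask IoU instance segmentation; the matcher
takes `iou_kind` explicitly.

Diagnosis agreement (`compare_diagnoses`) matches predicted to reference
lesions per image greedily by descending box IoU (diagnoses carry no
ranking score) and tallies: detected instances, fully correct
(severity ∧ tooth ∧ surface), severity-correct, tooth-correct,
surface-correct.

## Preprocessing

CLAHE follows the classic tiled algorithm: per-tile 256-bin histogram,
clipped at `max(1, clip_limit·tile_area/256)` with the clipped excess
redistributed uniformly (remainder spread over the lowest bins), per-tile
equalization LUTs, bilinear blending between tile centers. Defaults:
clip limit 1.4, 8×8 tiles — a gentle setting that improves lesion
visibility without amplifying noise. Images that tiles do not divide evenly
are reflect-padded and cropped back. The operation never touches
coordinates.

Resizing scales x and y independently (source radiographs ~3300×2550,
working size 1024×768 — different aspect ratios, no letterboxing), so every
annotation coordinate transforms by exactly (target/original) per axis and
the inverse resize recovers coordinates to 1e-6 px.

Flip augmentation emits original + horizontal + vertical flips (×3) for
train/val scenes; the test split is never augmented, so held-out counts
stay untouched. Derived scenes get `__hflip`/`__vflip` id suffixes.

## Dataset bookkeeping

Splitting is a seeded deterministic shuffle with floor-based val/test sizes
and the remainder to train: 1354 scenes at 80/10/10 give 1084/135/135.
YOLO text files use 6 decimal places, space separation, one object per
line, `<image_id>.txt`; out-of-frame vertices are an error, never silently
clipped, because clipping would corrupt the box/outline invariant. Tooth
detections travel in a sidecar TSV rather than inside the caries COCO file,
since tooth numbering is an external component.

## Synthetic scenes

The generator emulates what the assignment and evaluation stages actually
consume, not radiographic appearance. Per scene (deterministic under
(seed, index)): a 1024×768 frame, a random or fixed side, two rows of 4
axis-aligned tooth boxes (FDI positions 4–7 of the matching upper and lower
quadrants; widths 165–205 px, heights ~255–305 px), proximal gaps of a few
pixels, with a fraction of adjacent boxes overlapping by 10–16 px — as real
tooth detectors produce at contact points, and the only way the
complete-coverage scenario can arise. Each interior proximal gap hosts a
lesion with probability `lesion_rate` (default 0.15, ≈0.9 lesions per
scene); placement randomly realizes scenario-1, -2 or -3 geometry, and the
true tooth and surface are recorded at placement time from the anatomical
site (for the coverage scenario, by the same nearest-edge arithmetic
written out independently). Severities are drawn from the class mix, whose
default is the training-set proportion of a 5188-lesion clinical corpus
(RA : RB : RC = 1371 : 3275 : 542, used as exact fractions so they sum
to 1). Lesion outlines are 12-vertex ellipses inscribed in the lesion box,
so the box/outline invariant holds exactly.

With `edge_truncation > 0`, a row's terminal tooth may be cut by the frame
border (30–55 % of its width) and is then missed by the simulated numbering
model 60 % of the time — reproducing qualitatively the reported edge
failure mode, where a lesion's tooth goes undetected or a neighbor absorbs
it. A test asserts that *only* such edge-involved lesions are ever
misdiagnosed; with `edge_truncation = 0` the pipeline recovers 100 % of
ground-truth (tooth, surface) pairs, the desk-scale counterpart of perfect
localization on fully visible teeth.

What the generator does **not** model: anatomical crown curvature, overlap
shadows, cervical burnout, intensity realism (rendering is a crude
three-level sketch for I/O and CLAHE tests). Passing tests therefore
demonstrate correctness of the geometry, conventions and bookkeeping — not
detector performance on real radiographs.

The mock detector perturbs ground truth: per-lesion miss probability,
Gaussian translation + per-vertex jitter (boxes recomputed from the jittered
outlines), severity resampling through a row-stochastic confusion matrix,
Beta-distributed confidences (Beta(8,2) for true, Beta(2,5) for spurious
detections; a zero second parameter degenerates to a fixed 1.0), and
Poisson-many spurious lesions at random positions. Its per-scene RNG is
derived from (seed, CRC32(image_id)), so results are independent of
iteration order.

## Numerical and problem-size choices

- Acceptance-style checks run on 200 scenes (~170–200 lesions), threshold
  properties on 4–5 scenes × 10 seeds, the class-mix check on ~10,000
  lesions — sizes at which the whole suite completes in a few seconds while
  binomial 3σ bounds are already tight.
- Tolerances: box/outline 1e-6 px; complete-coverage 1e-6 relative;
  midpoint tie 1e-9 px; YOLO round-trip 1e-4 normalized units (6-decimal
  format); mask-vs-box IoU agreement 0.08 absolute.
- All ties anywhere (overlap areas, edge distances, matching order) break
  deterministically, ultimately by ascending FDI or input index.

## Known limitations

- Only mesial/distal surfaces are modeled (no occlusal/buccal/lingual),
  one surface per lesion, permanent dentition only.
- The mesial-direction display convention is a documented choice, not a
  fact recoverable from annotations; if a deployment's viewers mirror
  images differently, flip `MESIAL_X_SIGN`.
- AP uses all-point interpolation; COCO's 101-point variant would differ
  in the third decimal on small samples. The interpolation lives in one
  function (`_ap_from_ranked`) should a toggle be needed.
- Synthetic perfection (100 % assignment) is a statement about the
  algorithm under ideal detections, not about clinical accuracy.
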
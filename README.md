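# bitewing

Detector-agnostic tooling for **proximal caries diagnosis on bitewing
radiographs**. Proximal (interproximal) caries — decay on the mesial or
distal surfaces where adjacent teeth touch — is hard to see clinically and
is usually assessed on bitewing X-rays. A modern pipeline detects lesions
with an instance-segmentation network, numbers the teeth with a second
model, and then has to answer the clinically useful question: *which tooth,
and which of its surfaces, does each lesion affect, and how severe is it
(ICCMS™ RA / RB / RC)?*

`bitewing` implements everything around the neural networks, treating the
detectors as replaceable inputs:

- **Geometry & domain types** (`bitewing.scene`): boxes, polygons, frames,
  FDI-numbered tooth detections, caries detections with box/outline
  consistency enforced; box IoU, rasterized mask IoU, flips.
- **Annotation I/O** (`bitewing.annotation_io`): COCO JSON, YOLO
  segmentation/detection text dialects (bit-exact 6-decimal format),
  train/val/test splitting, per-class count tables, sidecar tooth tables
  and YAML manifests.
- **Preprocessing** (`bitewing.preprocessing`): CLAHE contrast enhancement
  (clip limit 1.4, 8×8 tiles), per-axis resize to 1024×768, flip
  augmentation that excludes the test split.
- **Lesion→tooth/surface assignment** (`bitewing.assignment`): for each
  lesion, the intersecting tooth boxes are resolved through three
  scenarios — single overlap; several overlaps with a strict area maximum;
  complete coverage by two or more teeth, decided by the nearest vertical
  box edge — and the affected surface (mesial/distal) follows from
  comparing box x-midpoints under the bitewing's side (left/right).
- **Evaluation** (`bitewing.evaluation`): greedy IoU matching with
  confidence filtering, per-class precision/recall/F1, all-point-interpolated
  AP, and macro mAP = (1/C)·Σᵢ APᵢ; threshold sweeps over
  IoU ∈ {0.5, 0.75} × confidence ∈ {0.001, 0.25, 0.5}; per-lesion
  diagnosis-agreement tallies.
- **Synthetic scenes** (`bitewing.synthetic`): a seeded generator of
  bitewing-like scenes (two rows of FDI-numbered tooth boxes, lesions
  placed at proximal surfaces with a clinically derived RA/RB/RC mix) with
  exact ground-truth diagnoses, plus a perturbation-based mock detector
  for studying threshold behavior without trained weights.

## Worked example

```sh
$ bitewing simulate --n 20 --seed 0 --out demo --lesion-rate 0.5
wrote 20 scenes, 62 lesions to demo
$ bitewing diagnose --manifest demo/manifest.yaml --out demo/diagnoses.tsv
wrote 62 diagnoses (0 undetermined) to demo/diagnoses.tsv
$ head -4 demo/diagnoses.tsv
image_id        caries_index    severity        tooth   surface
scene_0000      0       RA      16      distal
scene_0000      1       RA      47      mesial
scene_0000      2       RC      45      mesial
```

Each row says: lesion *caries_index* on image *image_id* has severity RA/RB/RC
and affects the given FDI tooth on its mesial or distal surface — e.g. an
initial-stage lesion on the distal surface of the upper-right first molar
(tooth 16). On fully visible teeth the assignment reproduces the generator's
ground truth exactly, which is why the demo reports 0 undetermined lesions.

Simulated detector output can be scored the same way a trained model would be:

```sh
$ bitewing mock-detect --manifest demo/manifest.yaml --seed 1 --out demo/preds.json
wrote 65 predictions to demo/preds.json
$ bitewing evaluate --manifest demo/manifest.yaml --pred demo/preds.json
iou_thr: 0.5
conf_thr: 0.25
...
macro:
  precision: 0.7882996632996632
  recall: 0.8698412698412699
  f1: 0.8044993734194789
  mAP: 0.7885120743454078
```

The macro block is the unweighted mean over the three severity classes at
the default operating point (IoU 0.5, confidence 0.25); `bitewing sweep`
produces the full threshold grid as TSV.

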
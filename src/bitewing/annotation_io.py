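"""Annotation file formats and dataset bookkeeping.

Three interchange dialects are supported:

* COCO: one JSON file with ``images``, ``annotations`` (polygon segmentation
  plus bbox) and ``categories`` (RA/RB/RC).
* YOLO-segmentation text: one ``<image_id>.txt`` per image; each line is the
  class id followed by the polygon vertices, normalized to [0, 1] by the
  frame width/height. Six decimal places, space-separated.
* YOLO-detection text: same, with the polygon replaced by the normalized
  x-center, y-center, width, height of the bounding box.

Tooth detections come from an external numbering model and are carried in a
sidecar TSV (image_id, fdi, x_min, y_min, x_max, y_max, confidence), never
inside the caries COCO file. A YAML manifest ties images, frame dimensions,
bitewing side, split tags and annotation files together.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import yaml

from .scene import (
    Box,
    CariesDetection,
    Frame,
    GeometryError,
    Polygon,
    Scene,
    Severity,
    Side,
    ToothDetection,
    polygon_to_box,
)


class FormatError(ValueError):
    """Raised for malformed annotation files."""


class CoordinateRangeError(ValueError):
    """Raised when a coordinate falls outside its frame (never silently clipped)."""


SPLITS = ("train", "val", "test", "unsplit")


@dataclass
class AnnotationSet:
    """A collection of scenes with per-scene split tags."""

    scenes: list[Scene]
    splits: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.image_id for s in self.scenes]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate image_ids: {dup[:5]}")
        for s in self.scenes:
            self.splits.setdefault(s.image_id, "unsplit")
        for image_id, tag in self.splits.items():
            if tag not in SPLITS:
                raise ValueError(f"unknown split tag {tag!r} for {image_id}")

    def __len__(self) -> int:
        return len(self.scenes)

    def scene(self, image_id: str) -> Scene:
        for s in self.scenes:
            if s.image_id == image_id:
                return s
        raise KeyError(image_id)

    def subset(self, split: str) -> "AnnotationSet":
        scenes = [s for s in self.scenes if self.splits[s.image_id] == split]
        return AnnotationSet(scenes, {s.image_id: split for s in scenes})


# ---------------------------------------------------------------------------
# COCO
# ---------------------------------------------------------------------------


def read_coco(path: str | Path, sides: Optional[Mapping[str, str]] = None) -> AnnotationSet:
    """Read a COCO annotation file into an AnnotationSet.

    Category names must map onto RA/RB/RC. Boxes are recomputed from the
    polygons, so bbox entries in the file are informational only. ``sides``
    optionally supplies the bitewing side per image id.
    """
    with open(path) as f:
        doc = json.load(f)
    try:
        images = doc["images"]
        annotations = doc["annotations"]
        categories = doc["categories"]
    except (KeyError, TypeError) as e:
        raise FormatError(f"{path}: not a COCO file (missing {e})") from None

    cat_map: dict[int, Severity] = {}
    for cat in categories:
        try:
            cat_map[cat["id"]] = Severity.from_label(cat["name"])
        except ValueError:
            raise FormatError(f"{path}: unknown category name {cat['name']!r}") from None

    per_image: dict[object, list[CariesDetection]] = {img["id"]: [] for img in images}
    for ann in annotations:
        img_id = ann["image_id"]
        if img_id not in per_image:
            raise FormatError(f"{path}: annotation references missing image id {img_id}")
        if ann["category_id"] not in cat_map:
            raise FormatError(f"{path}: annotation uses unknown category id {ann['category_id']}")
        seg = ann["segmentation"][0]
        verts = tuple(zip(seg[0::2], seg[1::2]))
        poly = Polygon(verts)
        conf = float(ann.get("score", 1.0))
        per_image[img_id].append(
            CariesDetection.from_polygon(cat_map[ann["category_id"]], poly, conf)
        )

    scenes = []
    for img in images:
        image_id = str(img.get("file_name", img["id"])).rsplit(".", 1)[0]
        side = Side((sides or {}).get(image_id, "unknown"))
        frame = Frame(int(img["width"]), int(img["height"]), side)
        scenes.append(Scene(image_id, frame, (), tuple(per_image[img["id"]])))
    return AnnotationSet(scenes)


def write_coco(aset: AnnotationSet, path: str | Path) -> None:
    """Write the caries annotations of an AnnotationSet as a COCO JSON file."""
    images, annotations = [], []
    ann_id = 1
    id_of = {s.image_id: i + 1 for i, s in enumerate(aset.scenes)}
    for s in aset.scenes:
        images.append(
            {
                "id": id_of[s.image_id],
                "file_name": f"{s.image_id}.png",
                "width": s.frame.width,
                "height": s.frame.height,
            }
        )
        for c in s.caries:
            seg = [float(v) for xy in c.polygon.vertices for v in xy]
            annotations.append(
                {
                    "id": ann_id,
                    "image_id": id_of[s.image_id],
                    "category_id": c.severity.class_id + 1,
                    "segmentation": [seg],
                    "bbox": [c.box.x_min, c.box.y_min, c.box.width, c.box.height],
                    "area": c.box.area,
                    "iscrowd": 0,
                    "score": c.confidence,
                }
            )
            ann_id += 1
    doc = {
        "images": images,
        "annotations": annotations,
        "categories": [
            {"id": sev.class_id + 1, "name": sev.label} for sev in Severity
        ],
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as f:
        json.dump(doc, f)


# ---------------------------------------------------------------------------
# YOLO text dialects
# ---------------------------------------------------------------------------


def _norm(value: float, extent: float, what: str, image_id: str) -> float:
    if value < 0 or value > extent:
        raise CoordinateRangeError(
            f"{image_id}: {what} {value} outside [0, {extent}] (refusing to clip)"
        )
    return value / extent


def write_yolo_seg(aset: AnnotationSet, out_dir: str | Path) -> None:
    """One normalized-polygon label file per image (empty when lesion-free)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in aset.scenes:
        w, h = s.frame.width, s.frame.height
        lines = []
        for c in s.caries:
            coords = []
            for x, y in c.polygon.vertices:
                coords.append(f"{_norm(x, w, 'x', s.image_id):.6f}")
                coords.append(f"{_norm(y, h, 'y', s.image_id):.6f}")
            lines.append(" ".join([str(c.severity.class_id), *coords]))
        (out / f"{s.image_id}.txt").write_text("".join(line + "\n" for line in lines))


def write_yolo_det(aset: AnnotationSet, out_dir: str | Path) -> None:
    """One normalized center-form bounding-box label file per image."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in aset.scenes:
        w, h = s.frame.width, s.frame.height
        lines = []
        for c in s.caries:
            _norm(c.box.x_min, w, "x", s.image_id)
            _norm(c.box.x_max, w, "x", s.image_id)
            _norm(c.box.y_min, h, "y", s.image_id)
            _norm(c.box.y_max, h, "y", s.image_id)
            fields = (
                c.box.x_center / w,
                c.box.y_center / h,
                c.box.width / w,
                c.box.height / h,
            )
            lines.append(
                " ".join([str(c.severity.class_id), *(f"{v:.6f}" for v in fields)])
            )
        (out / f"{s.image_id}.txt").write_text("".join(line + "\n" for line in lines))


def read_yolo_seg(label_dir: str | Path, frames: Mapping[str, Frame]) -> AnnotationSet:
    """Inverse of write_yolo_seg, up to 6-decimal normalization rounding.

    ``frames`` maps each image id (label file stem) to its Frame.
    """
    scenes = []
    for image_id, frame in frames.items():
        path = Path(label_dir) / f"{image_id}.txt"
        if not path.exists():
            raise FormatError(f"missing label file {path}")
        caries = []
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip():
                continue
            tokens = line.split()
            try:
                class_id = int(tokens[0])
                sev = Severity(class_id)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: unknown class id {tokens[0]!r}") from None
            coords = [float(t) for t in tokens[1:]]
            if len(coords) % 2 != 0 or len(coords) < 6:
                raise FormatError(
                    f"{path}:{lineno}: expected an even number (>=6) of coordinates, got {len(coords)}"
                )
            verts = tuple(
                (x * frame.width, y * frame.height)
                for x, y in zip(coords[0::2], coords[1::2])
            )
            caries.append(CariesDetection.from_polygon(sev, Polygon(verts)))
        scenes.append(Scene(image_id, frame, (), tuple(caries)))
    return AnnotationSet(scenes)


# ---------------------------------------------------------------------------
# splits and counts
# ---------------------------------------------------------------------------


def split_dataset(
    aset: AnnotationSet,
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> AnnotationSet:
    """Tag scenes train/val/test by a deterministic seeded shuffle.

    Split sizes are floor(n * ratio) for val and test, with the remainder
    going to train (so 1354 scenes at 80/10/10 give 1084/135/135).
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {ratios}")
    n = len(aset.scenes)
    n_val = math.floor(n * ratios[1])
    n_test = math.floor(n * ratios[2])
    n_train = n - n_val - n_test
    for size, ratio, name in ((n_train, ratios[0], "train"), (n_val, ratios[1], "val"), (n_test, ratios[2], "test")):
        if ratio > 0 and size == 0:
            raise ValueError(f"too few scenes ({n}) for a nonzero {name} split")
    ids = sorted(s.image_id for s in aset.scenes)
    random.Random(seed).shuffle(ids)
    splits = {}
    for i, image_id in enumerate(ids):
        if i < n_train:
            splits[image_id] = "train"
        elif i < n_train + n_val:
            splits[image_id] = "val"
        else:
            splits[image_id] = "test"
    return AnnotationSet(list(aset.scenes), splits)


@dataclass(frozen=True)
class CountRow:
    images: int
    ra: int
    rb: int
    rc: int

    @property
    def total(self) -> int:
        return self.ra + self.rb + self.rc


@dataclass(frozen=True)
class ClassCountTable:
    """Images and per-class lesion counts per split, plus grand totals."""

    rows: Mapping[str, CountRow]

    @property
    def total(self) -> CountRow:
        return CountRow(
            sum(r.images for r in self.rows.values()),
            sum(r.ra for r in self.rows.values()),
            sum(r.rb for r in self.rows.values()),
            sum(r.rc for r in self.rows.values()),
        )


def class_counts(aset: AnnotationSet) -> ClassCountTable:
    """Tally images and RA/RB/RC lesion counts per split."""
    rows = {}
    for split in SPLITS:
        scenes = [s for s in aset.scenes if aset.splits[s.image_id] == split]
        if not scenes and split == "unsplit":
            continue
        counts = {sev: 0 for sev in Severity}
        for s in scenes:
            for c in s.caries:
                counts[c.severity] += 1
        rows[split] = CountRow(
            len(scenes), counts[Severity.RA], counts[Severity.RB], counts[Severity.RC]
        )
    return ClassCountTable(rows)


# ---------------------------------------------------------------------------
# sidecar tooth table, diagnosis table, manifest
# ---------------------------------------------------------------------------

_TOOTH_HEADER = "image_id\tfdi\tx_min\ty_min\tx_max\ty_max\tconfidence"


def write_tooth_table(teeth: Mapping[str, Sequence[ToothDetection]], path: str | Path) -> None:
    lines = [_TOOTH_HEADER]
    for image_id in sorted(teeth):
        for t in teeth[image_id]:
            lines.append(
                f"{image_id}\t{t.fdi}\t{t.box.x_min:.3f}\t{t.box.y_min:.3f}"
                f"\t{t.box.x_max:.3f}\t{t.box.y_max:.3f}\t{t.confidence:.4f}"
            )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("".join(line + "\n" for line in lines))


def read_tooth_table(path: str | Path) -> dict[str, list[ToothDetection]]:
    out: dict[str, list[ToothDetection]] = {}
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != _TOOTH_HEADER:
        raise FormatError(f"{path}: missing tooth-table header")
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 7:
            raise FormatError(f"{path}:{lineno}: expected 7 tab-separated fields")
        image_id, fdi, x0, y0, x1, y1, conf = fields
        out.setdefault(image_id, []).append(
            ToothDetection(int(fdi), Box(float(x0), float(y0), float(x1), float(y1)), float(conf))
        )
    return out


def write_diagnosis_table(diagnoses: Mapping[str, Sequence], path: str | Path) -> None:
    """Diagnosis table TSV: image_id, caries_index, severity, tooth, surface."""
    lines = ["image_id\tcaries_index\tseverity\ttooth\tsurface"]
    for image_id in sorted(diagnoses):
        for d in diagnoses[image_id]:
            tooth = "undetermined" if d.tooth is None else str(d.tooth)
            lines.append(
                f"{image_id}\t{d.caries_index}\t{d.severity.label}\t{tooth}\t{d.surface.value}"
            )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("".join(line + "\n" for line in lines))


def read_diagnosis_table(path: str | Path) -> dict[str, list]:
    from .assignment import Diagnosis, Surface

    out: dict[str, list] = {}
    lines = Path(path).read_text().splitlines()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        image_id, idx, sev, tooth, surface = line.split("\t")
        out.setdefault(image_id, []).append(
            Diagnosis(
                int(idx),
                Severity.from_label(sev),
                None if tooth == "undetermined" else int(tooth),
                Surface(surface),
            )
        )
    return out


def write_manifest(
    aset: AnnotationSet,
    path: str | Path,
    coco: Optional[str] = None,
    teeth: Optional[str] = None,
    diagnoses: Optional[str] = None,
    images: Optional[Mapping[str, str]] = None,
) -> None:
    """YAML manifest listing images, frame dims, side and split per scene."""
    doc = {
        "images": [
            {
                "image_id": s.image_id,
                "width": s.frame.width,
                "height": s.frame.height,
                "side": s.frame.side.value,
                "split": aset.splits[s.image_id],
                **({"image": images[s.image_id]} if images and s.image_id in images else {}),
            }
            for s in aset.scenes
        ],
        "annotations": {
            k: v
            for k, v in (("coco", coco), ("teeth", teeth), ("diagnoses", diagnoses))
            if v is not None
        },
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as f:
        yaml.safe_dump(doc, f, sort_keys=False)


def load_dataset(manifest_path: str | Path) -> AnnotationSet:
    """Load a full AnnotationSet (caries + teeth + sides + splits) via its manifest."""
    manifest_path = Path(manifest_path)
    with open(manifest_path) as f:
        doc = yaml.safe_load(f)
    entries = {e["image_id"]: e for e in doc["images"]}
    base = manifest_path.parent
    ann = doc.get("annotations", {})
    if "coco" not in ann:
        raise FormatError(f"{manifest_path}: manifest lists no COCO annotation file")
    sides = {eid: e.get("side", "unknown") for eid, e in entries.items()}
    aset = read_coco(base / ann["coco"], sides=sides)
    teeth = read_tooth_table(base / ann["teeth"]) if "teeth" in ann else {}
    scenes = []
    for s in aset.scenes:
        if s.image_id not in entries:
            raise FormatError(f"{manifest_path}: COCO image {s.image_id} missing from manifest")
        scenes.append(
            Scene(s.image_id, s.frame, tuple(teeth.get(s.image_id, ())), s.caries)
        )
    splits = {eid: e.get("split", "unsplit") for eid, e in entries.items()}
    return AnnotationSet(scenes, splits)
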
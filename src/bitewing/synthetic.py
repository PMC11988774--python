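"""Synthetic bitewing scenes with ground-truth dental charts, plus a mock detector.

The generator emulates the geometry a bitewing radiograph presents to the
diagnostic pipeline: two horizontal rows of posterior teeth (one upper and
one lower quadrant of the same side), FDI-numbered tooth bounding boxes with
proximal gaps, and carious lesions placed at proximal surfaces. Lesion
placement deliberately produces all three tooth-overlap scenarios the
assignment module must resolve: lesions inside a single tooth near a
proximal edge, lesions straddling a gap with unequal overlap, and lesions
lying entirely inside the shared strip of two overlapping tooth boxes. The
true (tooth, surface, severity) of every lesion is recorded at placement
time from the anatomical site, independently of the assignment code.

Severity labels are drawn from the configured class mix, whose default is
the RA/RB/RC proportion of a 5188-lesion clinical training set
(1371 : 3275 : 542). A perturbation-based mock detector stands in for a
trained segmentation network so that threshold-sweep behavior can be
studied without any model weights.

Rendering is optional and deliberately crude (uniform background, brighter
tooth rectangles, darker lesion blobs) — enough for contrast-enhancement
and file round-trip tests, with no pretense of radiographic realism.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import annotation_io as aio
from .assignment import Diagnosis, Surface
from .scene import (
    Box,
    CariesDetection,
    Frame,
    Polygon,
    Scene,
    Severity,
    Side,
    ToothDetection,
    rasterize,
)

#: Default RA/RB/RC mix: training-set lesion proportions 1371/3275/542 of 5188.
DEFAULT_CLASS_MIX = (1371 / 5188, 3275 / 5188, 542 / 5188)

_IDENTITYISH = (
    (0.9, 0.05, 0.05),
    (0.05, 0.9, 0.05),
    (0.05, 0.05, 0.9),
)


@dataclass(frozen=True)
class SceneGenConfig:
    """Geometry, class mix and randomness of the synthetic scene generator."""

    side: str = "random"  # left | right | random
    teeth_per_row: int = 4  # FDI positions 4 .. 3+teeth_per_row
    frame_size: tuple[int, int] = (1024, 768)  # (width, height)
    lesion_rate: float = 0.15  # P(lesion) per interior proximal gap
    class_mix: tuple[float, float, float] = DEFAULT_CLASS_MIX
    proximal_gap: float = 6.0  # typical px gap between adjacent teeth
    overlap_gap_rate: float = 0.25  # P(adjacent tooth boxes overlap)
    edge_truncation: float = 0.0  # P(a row's terminal tooth is cut by the frame)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.side not in ("left", "right", "random"):
            raise ValueError(f"side must be left/right/random, got {self.side!r}")
        if not 1 <= self.teeth_per_row <= 5:
            raise ValueError("teeth_per_row must be in 1..5 (FDI positions 4-8)")
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")
        for p in (self.lesion_rate, self.overlap_gap_rate, self.edge_truncation, *self.class_mix):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        w, h = self.frame_size
        need_w = self.teeth_per_row * 210 + 70
        if w < need_w or h < 700:
            raise ValueError(
                f"frame {w}x{h} too small for {self.teeth_per_row} teeth per row"
            )


@dataclass(frozen=True)
class ConfidenceModel:
    """Beta-distribution parameters for true vs spurious detection scores.

    A zero ``b`` parameter degenerates to a fixed confidence of 1.0, which
    gives an exactly-perfect detector when all noise rates are zero.
    """

    true_a: float = 8.0
    true_b: float = 2.0
    spurious_a: float = 2.0
    spurious_b: float = 5.0

    def draw(self, rng: np.random.Generator, spurious: bool = False) -> float:
        a, b = (self.spurious_a, self.spurious_b) if spurious else (self.true_a, self.true_b)
        if b == 0:
            return 1.0
        return float(rng.beta(a, b))


@dataclass(frozen=True)
class PerturbationConfig:
    """Noise model of the mock detector standing in for a trained network."""

    box_jitter_sd: float = 1.0  # px, whole-lesion translation noise
    vertex_jitter_sd: float = 1.0  # px, per-vertex outline noise
    miss_rate: float = 0.1  # P(a true lesion is not detected)
    spurious_rate: float = 0.3  # expected false detections per image
    class_confusion: tuple[tuple[float, float, float], ...] = _IDENTITYISH
    conf_model: ConfidenceModel = field(default_factory=ConfidenceModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.miss_rate <= 1.0:
            raise ValueError("miss_rate must lie in [0, 1]")
        if self.spurious_rate < 0:
            raise ValueError("spurious_rate must be >= 0")
        for row in self.class_confusion:
            if abs(sum(row) - 1.0) > 1e-9:
                raise ValueError("class_confusion rows must sum to 1")


def _ellipse_polygon(xc: float, yc: float, w: float, h: float, n: int = 12) -> Polygon:
    """n-vertex ellipse inscribed in a w x h box; touches all four box sides."""
    theta = np.arange(n) * (2.0 * np.pi / n)
    verts = tuple(
        (xc + 0.5 * w * float(np.cos(t)), yc + 0.5 * h * float(np.sin(t))) for t in theta
    )
    return Polygon(verts)


def _row_fdis(side: Side, jaw: str, positions: Sequence[int]) -> list[int]:
    """FDI numbers for one row in left-to-right image order."""
    if side is Side.LEFT:
        quadrant = 2 if jaw == "upper" else 3
        ordered = list(positions)  # position increases with x (midline at -x)
    else:
        quadrant = 1 if jaw == "upper" else 4
        ordered = list(reversed(positions))  # midline at +x
    return [quadrant * 10 + p for p in ordered]


def _surface_for(gt_pos: int, other_pos: int) -> Surface:
    """Anatomical surface of the gap relative to the affected tooth."""
    return Surface.DISTAL if gt_pos < other_pos else Surface.MESIAL


def generate_scene(
    cfg: SceneGenConfig, index: int
) -> tuple[Scene, list[Diagnosis], None]:
    """Build one synthetic scene plus its ground-truth diagnoses.

    Deterministic under (cfg.seed, index). The third element of the return
    tuple is a placeholder for an optional rendering (see render_scene).
    """
    rng = np.random.default_rng([cfg.seed, index])
    W, H = cfg.frame_size
    side = Side(cfg.side) if cfg.side != "random" else (
        Side.LEFT if rng.random() < 0.5 else Side.RIGHT
    )
    n = cfg.teeth_per_row
    positions = list(range(4, 4 + n))

    teeth: list[ToothDetection] = []
    caries: list[CariesDetection] = []
    diagnoses: list[Diagnosis] = []

    y_top_upper = rng.uniform(35, 65)
    h_upper = rng.uniform(255, 305)
    y_top_lower = y_top_upper + h_upper + rng.uniform(30, 55)
    h_lower = rng.uniform(255, 300)

    for jaw, y_top, row_h in (("upper", y_top_upper, h_upper), ("lower", y_top_lower, h_lower)):
        widths = rng.uniform(165, 205, n)
        gaps = np.array(
            [
                -rng.uniform(10, 16)
                if rng.random() < cfg.overlap_gap_rate
                else rng.uniform(0.4, 1.5) * cfg.proximal_gap
                for _ in range(max(n - 1, 0))
            ]
        )
        x = rng.uniform(25, 60)
        boxes: list[Box] = []
        for i in range(n):
            y0 = y_top + rng.uniform(0, 8)
            y1 = y_top + row_h - rng.uniform(0, 8)
            boxes.append(Box(x, y0, x + widths[i], y1))
            if i < n - 1:
                x = x + widths[i] + gaps[i]

        # optionally truncate one terminal tooth at the frame edge; a partially
        # visible tooth is also prone to being missed by the numbering model
        dropped_idx: Optional[int] = None
        if n >= 2 and rng.random() < cfg.edge_truncation:
            cut_right = rng.random() < 0.5
            term = -1 if cut_right else 0
            if cut_right:
                cut = rng.uniform(0.3, 0.55) * boxes[-1].width
                shift = (W + cut) - boxes[-1].x_max
            else:
                cut = rng.uniform(0.3, 0.55) * boxes[0].width
                shift = -cut - boxes[0].x_min
            boxes = [b.translate(shift, 0.0) for b in boxes]
            boxes = [
                Box(max(b.x_min, 0.0), b.y_min, min(b.x_max, float(W)), b.y_max)
                for b in boxes
            ]
            if rng.random() < 0.6:
                dropped_idx = (n - 1) if cut_right else 0

        fdis = _row_fdis(side, jaw, positions)
        row_teeth = [ToothDetection(f, b) for f, b in zip(fdis, boxes)]
        teeth.extend(t for i, t in enumerate(row_teeth) if i != dropped_idx)

        # lesions at interior proximal gaps
        for gi in range(n - 1):
            if rng.random() >= cfg.lesion_rate:
                continue
            a, b = row_teeth[gi], row_teeth[gi + 1]
            placed = _place_lesion(rng, cfg, a, b, W)
            if placed is None:
                continue
            poly, gt_tooth, other_tooth = placed
            sev = Severity(int(rng.choice(3, p=cfg.class_mix)))
            det = CariesDetection.from_polygon(sev, poly)
            diagnoses.append(
                Diagnosis(
                    len(caries),
                    sev,
                    gt_tooth.fdi,
                    _surface_for(gt_tooth.position, other_tooth.position),
                )
            )
            caries.append(det)

    scene = Scene(
        f"scene_{index:04d}", Frame(W, H, side), tuple(teeth), tuple(caries)
    )
    return scene, diagnoses, None


def _place_lesion(
    rng: np.random.Generator,
    cfg: SceneGenConfig,
    a: ToothDetection,
    b: ToothDetection,
    frame_w: int,
) -> Optional[tuple[Polygon, ToothDetection, ToothDetection]]:
    """Place one lesion at the proximal gap between adjacent teeth a (left) and b.

    Returns (polygon, affected tooth, other tooth of the pair), or None when
    the local geometry leaves no room (e.g., a heavily truncated tooth).
    """
    y_lo = max(a.box.y_min, b.box.y_min) + 3.0
    y_hi = min(a.box.y_max, b.box.y_max) - 3.0
    if y_hi - y_lo < 30.0:
        return None
    h = rng.uniform(18.0, min(40.0, y_hi - y_lo - 6.0))
    yc = rng.uniform(y_lo + h / 2 + 1.0, y_hi - h / 2 - 1.0)

    gapw = b.box.x_min - a.box.x_max
    if gapw >= 0.0:  # separated teeth
        if rng.random() < 0.45:  # scenario 1: inside one tooth, hugging the gap edge
            t = a if rng.random() < 0.5 else b
            w = rng.uniform(14.0, 30.0)
            margin = rng.uniform(1.0, 4.0)
            if t.box.width < w + margin + 4.0:
                return None
            if t is a:
                x_max = a.box.x_max - margin
                x_min = x_max - w
            else:
                x_min = b.box.x_min + margin
                x_max = x_min + w
            other = b if t is a else a
        else:  # scenario 2: straddles the gap, strictly larger overlap with t
            t = a if rng.random() < 0.5 else b
            ov_t = rng.uniform(8.0, 16.0)
            ov_o = rng.uniform(2.0, min(6.0, ov_t - 2.0))
            if a.box.width < ov_t + 4.0 or b.box.width < ov_t + 4.0:
                return None
            if t is a:
                x_min = a.box.x_max - ov_t
                x_max = b.box.x_min + ov_o
            else:
                x_min = a.box.x_max - ov_o
                x_max = b.box.x_min + ov_t
            other = b if t is a else a
    else:  # overlapping tooth boxes; shared strip [b.x_min, a.x_max]
        sw = -gapw
        if rng.random() < 0.6:  # scenario 3: lesion entirely inside the strip
            w = rng.uniform(max(4.0, 0.35 * sw), 0.7 * sw)
            lo = b.box.x_min + 0.15 * sw + w / 2
            hi = b.box.x_min + 0.85 * sw - w / 2
            xc = rng.uniform(lo, hi)
            da = min(abs(xc - a.box.x_min), abs(xc - a.box.x_max))
            db = min(abs(xc - b.box.x_min), abs(xc - b.box.x_max))
            if da == db:
                xc += 0.37  # break the measure-zero tie deterministically
                da = min(abs(xc - a.box.x_min), abs(xc - a.box.x_max))
                db = min(abs(xc - b.box.x_min), abs(xc - b.box.x_max))
            if da < db or (da == db and a.fdi < b.fdi):
                t, other = a, b
            else:
                t, other = b, a
            x_min, x_max = xc - w / 2, xc + w / 2
        else:  # scenario 2: strip partially covered, extends into one tooth
            t = a if rng.random() < 0.5 else b
            inner = rng.uniform(0.3, 0.7) * sw
            ext = rng.uniform(6.0, 14.0)
            if t is a:
                x_min = b.box.x_min - ext
                x_max = b.box.x_min + inner
                if x_min < a.box.x_min + 2.0:
                    return None
            else:
                x_min = a.box.x_max - inner
                x_max = a.box.x_max + ext
                if x_max > b.box.x_max - 2.0:
                    return None
            other = b if t is a else a

    if x_min < 1.0 or x_max > frame_w - 1.0:
        return None
    w = x_max - x_min
    poly = _ellipse_polygon((x_min + x_max) / 2, yc, w, h)
    return poly, t, other


def generate_dataset(
    cfg: SceneGenConfig,
    n_images: int,
    out_dir: str | Path,
    render: bool = False,
) -> tuple[aio.AnnotationSet, dict[str, list[Diagnosis]]]:
    """Generate scenes and write the full on-disk dataset.

    Writes a COCO file, YOLO-seg and YOLO-det label directories, the sidecar
    tooth table, the ground-truth diagnosis table, a YAML manifest and
    (optionally) crude rendered PNGs.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    scenes, diag_map = [], {}
    for i in range(n_images):
        scene, diags, _ = generate_scene(cfg, i)
        scenes.append(scene)
        diag_map[scene.image_id] = diags
    aset = aio.AnnotationSet(scenes)

    aio.write_coco(aset, out / "annotations.json")
    aio.write_yolo_seg(aset, out / "labels_seg")
    aio.write_yolo_det(aset, out / "labels_det")
    aio.write_tooth_table({s.image_id: s.teeth for s in scenes}, out / "teeth.tsv")
    aio.write_diagnosis_table(diag_map, out / "diagnoses.tsv")

    images = None
    if render:
        from .preprocessing import save_image

        images = {}
        for s in scenes:
            save_image(render_scene(s), out / "images" / f"{s.image_id}.png")
            images[s.image_id] = f"images/{s.image_id}.png"

    aio.write_manifest(
        aset,
        out / "manifest.yaml",
        coco="annotations.json",
        teeth="teeth.tsv",
        diagnoses="diagnoses.tsv",
        images=images,
    )
    return aset, diag_map


def render_scene(scene: Scene, rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Crude grayscale rendering: dark background, bright teeth, darker lesions."""
    if rng is None:
        rng = np.random.default_rng(zlib.crc32(scene.image_id.encode()))
    img = np.full((scene.frame.height, scene.frame.width), 60, dtype=np.uint8)
    for t in scene.teeth:
        j0, j1 = int(t.box.y_min), int(np.ceil(t.box.y_max))
        i0, i1 = int(t.box.x_min), int(np.ceil(t.box.x_max))
        img[j0:j1, i0:i1] = 140 + int(rng.integers(0, 30))
    for c in scene.caries:
        img[rasterize(c.polygon, scene.frame)] = 75
    noise = rng.normal(0.0, 4.0, img.shape)
    return np.clip(img.astype(float) + noise, 0, 255).astype(np.uint8)


def mock_detect(scene: Scene, p: PerturbationConfig) -> list[CariesDetection]:
    """Simulate detector output for a scene: misses, jitter, confusion, spurious hits.

    Deterministic under (p.seed, scene.image_id), independent of call order.
    """
    rng = np.random.default_rng([p.seed, zlib.crc32(scene.image_id.encode())])
    W, H = scene.frame.width, scene.frame.height
    cm = p.conf_model
    preds: list[CariesDetection] = []

    for c in scene.caries:
        if rng.random() < p.miss_rate:
            continue
        dx, dy = rng.normal(0.0, p.box_jitter_sd, 2)
        verts = np.asarray(c.polygon.vertices, dtype=float)
        verts += np.array([dx, dy])
        verts += rng.normal(0.0, p.vertex_jitter_sd, verts.shape)
        verts[:, 0] = np.clip(verts[:, 0], 0.5, W - 0.5)
        verts[:, 1] = np.clip(verts[:, 1], 0.5, H - 0.5)
        sev = Severity(int(rng.choice(3, p=p.class_confusion[c.severity.class_id])))
        conf = cm.draw(rng)
        try:
            preds.append(
                CariesDetection.from_polygon(sev, Polygon(tuple(map(tuple, verts))), conf)
            )
        except ValueError:
            continue  # jitter collapsed the outline; treat as a miss

    for _ in range(int(rng.poisson(p.spurious_rate))):
        w = rng.uniform(10.0, 28.0)
        h = rng.uniform(14.0, 34.0)
        xc = rng.uniform(w / 2 + 1.0, W - w / 2 - 1.0)
        yc = rng.uniform(h / 2 + 1.0, H - h / 2 - 1.0)
        sev = Severity(int(rng.integers(0, 3)))
        conf = cm.draw(rng, spurious=True)
        preds.append(CariesDetection.from_polygon(sev, _ellipse_polygon(xc, yc, w, h), conf))
    return preds
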
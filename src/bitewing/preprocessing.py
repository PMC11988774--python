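"""Image enhancement and geometry-preserving dataset transforms.

CLAHE (contrast-limited adaptive histogram equalization) is applied as a
pure image operation before any geometry work: the image is divided into a
grid of tiles, each tile's 256-bin histogram is clipped at
``clip_limit * tile_area / 256`` with the excess redistributed uniformly,
and the per-tile equalization lookup tables are blended bilinearly between
neighboring tile centers so tile seams are invisible. The clip limit is the
familiar multiplicative factor (default 1.4 on an 8x8 tile grid).

Resizing scales x and y independently (no letterboxing): source radiographs
are nominally 3300x2550 and the working resolution 1024x768, which have
different aspect ratios, so plain per-axis scaling is what keeps annotation
coordinates reproducible.

Flip augmentation triples the train/val data (original + horizontal flip +
vertical flip); the test split is left untouched so evaluation stays on
unaugmented scenes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from PIL import Image

from .annotation_io import AnnotationSet
from .scene import Box, CariesDetection, Frame, Polygon, Scene, ToothDetection, flip_scene


@dataclass(frozen=True)
class PreprocessConfig:
    clip_limit: float = 1.4
    tile_grid: tuple[int, int] = (8, 8)
    target_size: tuple[int, int] = (1024, 768)  # (width, height)

    def __post_init__(self) -> None:
        if self.clip_limit <= 0:
            raise ValueError("clip_limit must be > 0")
        if min(self.tile_grid) < 1 or min(self.target_size) < 1:
            raise ValueError("tile_grid and target_size entries must be >= 1")


def clahe_enhance(image: np.ndarray, cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization of an 8-bit image.

    Deterministic, shape-preserving; input must be a single-channel uint8
    array. Tiles that do not divide the image evenly are handled by
    reflective padding on the bottom/right, cropped away at the end.
    """
    if image.ndim != 2:
        raise ValueError(f"expected a single-channel image, got shape {image.shape}")
    if image.dtype != np.uint8:
        raise ValueError(f"expected uint8 input, got {image.dtype}")
    rows, cols = cfg.tile_grid
    h, w = image.shape
    th = -(-h // rows)  # tile height, ceil division
    tw = -(-w // cols)
    pad_h, pad_w = th * rows - h, tw * cols - w
    padded = np.pad(image, ((0, pad_h), (0, pad_w)), mode="reflect")

    tiles = padded.reshape(rows, th, cols, tw).transpose(0, 2, 1, 3)
    area = th * tw
    # per-tile histograms, vectorized over the (rows*cols) tiles
    flat = tiles.reshape(rows * cols, area)
    hist = np.zeros((rows * cols, 256), dtype=np.int64)
    for t in range(rows * cols):
        hist[t] = np.bincount(flat[t], minlength=256)

    clip = max(1, int(cfg.clip_limit * area / 256))
    excess = np.clip(hist - clip, 0, None).sum(axis=1)
    hist = np.minimum(hist, clip)
    hist += (excess // 256)[:, None]
    # spread the remainder over the first (excess mod 256) bins
    residual = excess % 256
    bin_idx = np.arange(256)[None, :]
    hist += (bin_idx < residual[:, None]).astype(np.int64)

    scale = 255.0 / area
    luts = np.rint(np.cumsum(hist, axis=1) * scale).clip(0, 255).astype(np.uint8)
    luts = luts.reshape(rows, cols, 256)

    # bilinear interpolation between tile-center LUTs
    H, W = padded.shape
    fy = (np.arange(H) + 0.5) / th - 0.5
    fx = (np.arange(W) + 0.5) / tw - 0.5
    y0 = np.clip(np.floor(fy).astype(int), 0, rows - 1)
    x0 = np.clip(np.floor(fx).astype(int), 0, cols - 1)
    y1 = np.minimum(y0 + 1, rows - 1)
    x1 = np.minimum(x0 + 1, cols - 1)
    wy = np.clip(fy - y0, 0.0, 1.0)[:, None]
    wx = np.clip(fx - x0, 0.0, 1.0)[None, :]

    img = padded
    gy0 = y0[:, None]
    gy1 = y1[:, None]
    gx0 = x0[None, :]
    gx1 = x1[None, :]
    v00 = luts[gy0, gx0, img].astype(np.float64)
    v01 = luts[gy0, gx1, img].astype(np.float64)
    v10 = luts[gy1, gx0, img].astype(np.float64)
    v11 = luts[gy1, gx1, img].astype(np.float64)
    out = (
        v00 * (1 - wy) * (1 - wx)
        + v01 * (1 - wy) * wx
        + v10 * wy * (1 - wx)
        + v11 * wy * wx
    )
    return np.rint(out[:h, :w]).clip(0, 255).astype(np.uint8)


def _scale_scene(scene: Scene, sx: float, sy: float, new_frame: Frame) -> Scene:
    teeth = tuple(
        ToothDetection(
            t.fdi,
            Box(t.box.x_min * sx, t.box.y_min * sy, t.box.x_max * sx, t.box.y_max * sy),
            t.confidence,
        )
        for t in scene.teeth
    )
    caries = tuple(
        CariesDetection.from_polygon(
            c.severity,
            Polygon(tuple((x * sx, y * sy) for x, y in c.polygon.vertices)),
            c.confidence,
        )
        for c in scene.caries
    )
    return Scene(scene.image_id, new_frame, teeth, caries)


def resize_scene(
    image: Optional[np.ndarray],
    scene: Scene,
    cfg: PreprocessConfig = PreprocessConfig(),
) -> tuple[Optional[np.ndarray], Scene]:
    """Resample an image to the target size and rescale the scene geometry.

    x coordinates scale by target_width/orig_width and y by
    target_height/orig_height, independently. ``image`` may be None to
    transform coordinates only.
    """
    tw, th = cfg.target_size
    if image is not None:
        if image.shape[:2] != (scene.frame.height, scene.frame.width):
            raise ValueError(
                f"image shape {image.shape[:2]} does not match frame "
                f"{scene.frame.height}x{scene.frame.width}"
            )
        image = np.asarray(
            Image.fromarray(image).resize((tw, th), resample=Image.BILINEAR)
        )
    sx = tw / scene.frame.width
    sy = th / scene.frame.height
    new_frame = Frame(tw, th, scene.frame.side)
    return image, _scale_scene(scene, sx, sy, new_frame)


def augment_flips(
    aset: AnnotationSet, splits: Optional[Sequence[str]] = None
) -> AnnotationSet:
    """Add horizontal- and vertical-flip copies of the selected scenes.

    By default every split except ``test`` is augmented (evaluation data is
    never synthetically enlarged); pass ``splits`` explicitly to override.
    Derived scenes get ``<id>__hflip`` / ``<id>__vflip`` ids and keep their
    originator's split tag.
    """
    if splits is None:
        splits = ("train", "val", "unsplit")
    scenes: list[Scene] = []
    tags: dict[str, str] = {}
    for s in aset.scenes:
        tag = aset.splits[s.image_id]
        scenes.append(s)
        tags[s.image_id] = tag
        if tag not in splits:
            continue
        for axis, suffix in (("horizontal", "__hflip"), ("vertical", "__vflip")):
            flipped = flip_scene(s, axis)
            flipped = Scene(s.image_id + suffix, flipped.frame, flipped.teeth, flipped.caries)
            scenes.append(flipped)
            tags[flipped.image_id] = tag
    return AnnotationSet(scenes, tags)


def load_image(path: str | Path) -> np.ndarray:
    """Read an image file as 8-bit grayscale."""
    return np.asarray(Image.open(path).convert("L"))


def save_image(image: np.ndarray, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(image).save(path)
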
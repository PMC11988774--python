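"""Core domain types and planar geometry for bitewing radiograph scenes.

Coordinate convention: continuous pixel coordinates, origin at the top-left
corner of the image, x increasing rightward, y increasing downward. Boxes are
stored in corner form (x_min, y_min, x_max, y_max) and treated as closed real
intervals; center-form (YOLO) coordinates exist only at file I/O boundaries.

FDI two-digit tooth numbering is used throughout: the first digit is the
quadrant (1 upper-right, 2 upper-left, 3 lower-left, 4 lower-right), the
second the position from the dental midline (1-8).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon as _ShapelyPolygon


class GeometryError(ValueError):
    """Raised for degenerate or invalid geometric input."""


class UndefinedIoUError(GeometryError):
    """Raised when an IoU is requested between two empty rasters."""


#: FDI numbers of permanent teeth, quadrant 1-4, position 1-8.
VALID_FDI = frozenset(
    q * 10 + p for q in (1, 2, 3, 4) for p in range(1, 9)
)


class Severity(enum.IntEnum):
    """ICCMS radiographic caries severity stage.

    RA = initial (outer enamel / outer third of dentine), RB = moderate,
    RC = extensive. The integer value is the detector class id.
    """

    RA = 0
    RB = 1
    RC = 2

    @property
    def label(self) -> str:
        return self.name

    @property
    def class_id(self) -> int:
        return int(self)

    @classmethod
    def from_label(cls, label: str) -> "Severity":
        try:
            return cls[label]
        except KeyError:
            raise ValueError(f"unknown severity label {label!r}; expected RA, RB or RC") from None


class Side(str, enum.Enum):
    """Which side of the mouth a bitewing captures."""

    LEFT = "left"
    RIGHT = "right"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class Box:
    """Axis-aligned box in corner form; must have strictly positive area."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise GeometryError(
                f"degenerate box ({self.x_min}, {self.y_min}, {self.x_max}, {self.y_max})"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def x_center(self) -> float:
        return 0.5 * (self.x_min + self.x_max)

    @property
    def y_center(self) -> float:
        return 0.5 * (self.y_min + self.y_max)

    def translate(self, dx: float, dy: float) -> "Box":
        return Box(self.x_min + dx, self.y_min + dy, self.x_max + dx, self.y_max + dy)

    def contains_point(self, x: float, y: float) -> bool:
        return self.x_min <= x <= self.x_max and self.y_min <= y <= self.y_max


@dataclass(frozen=True)
class Polygon:
    """Implicitly closed polygon with at least 3 vertices and nonzero area."""

    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        object.__setattr__(self, "vertices", verts)
        if len(verts) < 3:
            raise GeometryError(f"polygon needs >=3 vertices, got {len(verts)}")
        if _shoelace(verts) == 0.0:
            raise GeometryError("polygon has zero shoelace area")

    def translate(self, dx: float, dy: float) -> "Polygon":
        return Polygon(tuple((x + dx, y + dy) for x, y in self.vertices))

    def as_shapely(self) -> _ShapelyPolygon:
        return _ShapelyPolygon(self.vertices)


@dataclass(frozen=True)
class Frame:
    """Image extent in pixels plus the bitewing side (left/right/unknown)."""

    width: int
    height: int
    side: Side = Side.UNKNOWN

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise GeometryError(f"frame dims must be positive, got {self.width}x{self.height}")
        object.__setattr__(self, "side", Side(self.side))


@dataclass(frozen=True)
class ToothDetection:
    """One tooth bounding box with its FDI number, from any numbering model."""

    fdi: int
    box: Box
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if self.fdi not in VALID_FDI:
            raise ValueError(f"invalid FDI tooth number {self.fdi}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")

    @property
    def quadrant(self) -> int:
        return self.fdi // 10

    @property
    def position(self) -> int:
        return self.fdi % 10


# Maximum allowed |box - polygon bounds| discrepancy, in pixels.
BOX_POLYGON_TOL = 1e-6


@dataclass(frozen=True)
class CariesDetection:
    """A carious-lesion instance: severity, polygon outline, derived box, score."""

    severity: Severity
    polygon: Polygon
    box: Box
    confidence: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "severity", Severity(self.severity))
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")
        bounds = polygon_to_box(self.polygon)
        if (
            abs(bounds.x_min - self.box.x_min) > BOX_POLYGON_TOL
            or abs(bounds.y_min - self.box.y_min) > BOX_POLYGON_TOL
            or abs(bounds.x_max - self.box.x_max) > BOX_POLYGON_TOL
            or abs(bounds.y_max - self.box.y_max) > BOX_POLYGON_TOL
        ):
            raise GeometryError("caries box does not match its polygon bounds")

    @classmethod
    def from_polygon(
        cls, severity: Severity, polygon: Polygon, confidence: float = 1.0
    ) -> "CariesDetection":
        return cls(severity, polygon, polygon_to_box(polygon), confidence)


@dataclass(frozen=True)
class Scene:
    """One bitewing image's worth of geometry: frame, teeth, caries."""

    image_id: str
    frame: Frame
    teeth: tuple[ToothDetection, ...] = ()
    caries: tuple[CariesDetection, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "teeth", tuple(self.teeth))
        object.__setattr__(self, "caries", tuple(self.caries))
        w, h = self.frame.width, self.frame.height
        for t in self.teeth:
            _check_in_frame(t.box, w, h, f"tooth {t.fdi}")
        for i, c in enumerate(self.caries):
            _check_in_frame(c.box, w, h, f"caries #{i}")


def _check_in_frame(box: Box, w: int, h: int, what: str) -> None:
    if box.x_min < 0 or box.y_min < 0 or box.x_max > w or box.y_max > h:
        raise GeometryError(f"{what} box outside frame {w}x{h}: {box}")


def _shoelace(verts: Sequence[tuple[float, float]]) -> float:
    a = np.asarray(verts, dtype=float)
    x, y = a[:, 0], a[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


# ---------------------------------------------------------------------------
# geometry operations
# ---------------------------------------------------------------------------


def intersection_area(a: Box, b: Box) -> float:
    """Area of the intersection of two boxes (0 when disjoint)."""
    w = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    h = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if w <= 0.0 or h <= 0.0:
        return 0.0
    return w * h


def box_iou(a: Box, b: Box) -> float:
    """Intersection over union of two boxes, in [0, 1]."""
    inter = intersection_area(a, b)
    union = a.area + b.area - inter
    return inter / union


def polygon_area(p: Polygon) -> float:
    """Absolute shoelace area of a polygon (orientation-independent)."""
    return abs(_shoelace(p.vertices))


def polygon_to_box(p: Polygon) -> Box:
    """Tight axis-aligned bounding box of a polygon's vertices."""
    xs = [v[0] for v in p.vertices]
    ys = [v[1] for v in p.vertices]
    return Box(min(xs), min(ys), max(xs), max(ys))


def rasterize(p: Polygon, frame: Frame) -> np.ndarray:
    """Boolean mask of a polygon on the frame's pixel grid.

    A pixel (row j, column i) belongs to the mask iff its center
    (i + 0.5, j + 0.5) lies inside or on the polygon boundary.
    """
    mask = np.zeros((frame.height, frame.width), dtype=bool)
    b = polygon_to_box(p)
    i0 = max(int(np.floor(b.x_min - 0.5)), 0)
    i1 = min(int(np.ceil(b.x_max + 0.5)), frame.width)
    j0 = max(int(np.floor(b.y_min - 0.5)), 0)
    j1 = min(int(np.ceil(b.y_max + 0.5)), frame.height)
    if i0 >= i1 or j0 >= j1:
        return mask
    xs = np.arange(i0, i1) + 0.5
    ys = np.arange(j0, j1) + 0.5
    gx, gy = np.meshgrid(xs, ys)
    inside = shapely.intersects_xy(p.as_shapely(), gx.ravel(), gy.ravel())
    mask[j0:j1, i0:i1] = inside.reshape(gy.shape)
    return mask


def mask_iou(p: Polygon, q: Polygon, frame: Frame) -> float:
    """IoU of two polygons' rasterized masks on the frame grid."""
    mp = rasterize(p, frame)
    mq = rasterize(q, frame)
    union = int(np.count_nonzero(mp | mq))
    if union == 0:
        raise UndefinedIoUError("both polygons rasterize to empty masks")
    inter = int(np.count_nonzero(mp & mq))
    return inter / union


def flip_box(box: Box, axis: str, extent: float) -> Box:
    if axis == "horizontal":
        return Box(extent - box.x_max, box.y_min, extent - box.x_min, box.y_max)
    if axis == "vertical":
        return Box(box.x_min, extent - box.y_max, box.x_max, extent - box.y_min)
    raise ValueError(f"unknown flip axis {axis!r}; expected 'horizontal' or 'vertical'")


def flip_polygon(p: Polygon, axis: str, extent: float) -> Polygon:
    if axis == "horizontal":
        return Polygon(tuple((extent - x, y) for x, y in p.vertices))
    if axis == "vertical":
        return Polygon(tuple((x, extent - y) for x, y in p.vertices))
    raise ValueError(f"unknown flip axis {axis!r}; expected 'horizontal' or 'vertical'")


def flip_scene(s: Scene, axis: str) -> Scene:
    """Mirror a scene about the vertical (axis='horizontal') or horizontal axis.

    A horizontal flip maps x -> width - x and toggles the bitewing side
    (left <-> right); a vertical flip maps y -> height - y and leaves the
    side unchanged. Severity labels and FDI numbers are untouched.
    """
    if axis == "horizontal":
        extent = float(s.frame.width)
        side = {Side.LEFT: Side.RIGHT, Side.RIGHT: Side.LEFT}.get(s.frame.side, Side.UNKNOWN)
    elif axis == "vertical":
        extent = float(s.frame.height)
        side = s.frame.side
    else:
        raise ValueError(f"unknown flip axis {axis!r}; expected 'horizontal' or 'vertical'")
    frame = Frame(s.frame.width, s.frame.height, side)
    teeth = tuple(
        ToothDetection(t.fdi, flip_box(t.box, axis, extent), t.confidence) for t in s.teeth
    )
    caries = tuple(
        CariesDetection(
            c.severity, flip_polygon(c.polygon, axis, extent), flip_box(c.box, axis, extent), c.confidence
        )
        for c in s.caries
    )
    return Scene(s.image_id, frame, teeth, caries)
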
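"""Assign each detected carious lesion to an affected tooth and surface.

Tooth assignment works on bounding boxes only and resolves one of three
overlap scenarios per lesion:

1. the lesion's box intersects exactly one tooth box -> that tooth;
2. it intersects several teeth with strictly different overlap areas ->
   the tooth with the largest intersection area;
3. it is completely covered by two or more tooth boxes (or the largest
   overlap areas are exactly tied) -> the tooth whose nearest vertical box
   edge is horizontally closest to the lesion's box center.

A lesion that intersects no tooth box is left undetermined (a value, not an
error) — this is the expected failure mode for teeth truncated at the image
edge.

The affected surface (mesial = toward the dental midline, distal = away
from it) is read off by comparing the x-midpoint of the lesion's box with
the x-midpoint of the assigned tooth's box, taking the bitewing side into
account. The side-to-direction convention lives in MESIAL_X_SIGN: on a
right-side bitewing the midline lies toward +x, on a left-side bitewing
toward -x. The opposite display convention is a one-line change.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .scene import (
    Box,
    CariesDetection,
    Frame,
    Scene,
    Severity,
    Side,
    ToothDetection,
    intersection_area,
)

#: Sign of the x direction that points toward the dental midline (mesial),
#: per bitewing side. Single configurable constant implementing the
#: surface-orientation convention.
MESIAL_X_SIGN: dict[Side, int] = {Side.RIGHT: +1, Side.LEFT: -1}

#: x-midpoint ties closer than this are reported as undetermined surface.
_MIDPOINT_TOL = 1e-9


class Surface(str, enum.Enum):
    MESIAL = "mesial"
    DISTAL = "distal"
    UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class Diagnosis:
    """Per-lesion result: affected FDI tooth (None = undetermined) and surface."""

    caries_index: int
    severity: Severity
    tooth: Optional[int]
    surface: Surface
    reason: Optional[str] = None

    def __post_init__(self) -> None:
        if self.tooth is None and self.surface is not Surface.UNDETERMINED:
            raise ValueError("surface must be undetermined when the tooth is undetermined")


@dataclass(frozen=True)
class AssignmentConfig:
    """Numeric thresholds for the overlap scenarios.

    complete_overlap_tol: relative slack on "the lesion box is fully covered
    by a tooth box" (scenario 3); exact containment is numerically fragile.
    min_overlap_area: intersection areas at or below this (px^2) count as no
    overlap at all.
    """

    complete_overlap_tol: float = 1e-6
    min_overlap_area: float = 0.0

    def __post_init__(self) -> None:
        if self.complete_overlap_tol < 0 or self.min_overlap_area < 0:
            raise ValueError("tolerances must be >= 0")


def overlapping_teeth(
    c: CariesDetection,
    teeth: Sequence[ToothDetection],
    cfg: AssignmentConfig = AssignmentConfig(),
) -> list[tuple[ToothDetection, float]]:
    """Teeth whose boxes intersect the lesion box, sorted by overlap area.

    Sort is by descending intersection area, ties broken by ascending FDI,
    so the result is deterministic for any input order.
    """
    hits = [
        (t, intersection_area(c.box, t.box))
        for t in teeth
        if intersection_area(c.box, t.box) > cfg.min_overlap_area
    ]
    hits.sort(key=lambda ta: (-ta[1], ta[0].fdi))
    return hits


def _nearest_edge_distance(cx: float, box: Box) -> float:
    """Horizontal distance from x=cx to the nearer vertical edge of a box."""
    return min(abs(cx - box.x_min), abs(cx - box.x_max))


def assign_tooth(
    c: CariesDetection,
    teeth: Sequence[ToothDetection],
    cfg: AssignmentConfig = AssignmentConfig(),
) -> Optional[int]:
    """Resolve the affected tooth via the three overlap scenarios.

    Returns the FDI number, or None when no tooth box overlaps the lesion.
    """
    hits = overlapping_teeth(c, teeth, cfg)
    if not hits:
        return None
    if len(hits) == 1:
        return hits[0][0].fdi

    need = (1.0 - cfg.complete_overlap_tol) * c.box.area
    complete = [t for t, a in hits if a >= need]
    if len(complete) >= 2:
        candidates = complete
    elif hits[0][1] > hits[1][1]:
        return hits[0][0].fdi
    else:
        top = hits[0][1]
        candidates = [t for t, a in hits if a == top]

    cx = c.box.x_center
    return min(candidates, key=lambda t: (_nearest_edge_distance(cx, t.box), t.fdi)).fdi


def determine_surface(
    c: CariesDetection, tooth: ToothDetection, side: Side
) -> Surface:
    """Mesial/distal from the x-midpoint rule, given the bitewing side."""
    if side is Side.UNKNOWN:
        return Surface.UNDETERMINED
    dx = c.box.x_center - tooth.box.x_center
    if abs(dx) <= _MIDPOINT_TOL:
        return Surface.UNDETERMINED
    return Surface.MESIAL if (dx > 0) == (MESIAL_X_SIGN[side] > 0) else Surface.DISTAL


def infer_side(teeth: Sequence[ToothDetection]) -> Side:
    """Infer the bitewing side from FDI quadrants by majority vote.

    Quadrants 1 and 4 are the patient's right side, 2 and 3 the left;
    an empty list or an exact tie yields unknown.
    """
    votes = Counter(
        Side.RIGHT if t.quadrant in (1, 4) else Side.LEFT for t in teeth
    )
    if votes[Side.RIGHT] > votes[Side.LEFT]:
        return Side.RIGHT
    if votes[Side.LEFT] > votes[Side.RIGHT]:
        return Side.LEFT
    return Side.UNKNOWN


def diagnose_scene(
    s: Scene, cfg: AssignmentConfig = AssignmentConfig()
) -> list[Diagnosis]:
    """One Diagnosis per caries detection, in input order.

    The bitewing side comes from the frame when known, otherwise it is
    inferred from the FDI quadrants of the tooth detections.
    """
    side = s.frame.side
    if side is Side.UNKNOWN:
        side = infer_side(s.teeth)
    by_fdi = {t.fdi: t for t in s.teeth}
    out: list[Diagnosis] = []
    for i, c in enumerate(s.caries):
        fdi = assign_tooth(c, s.teeth, cfg)
        if fdi is None:
            out.append(
                Diagnosis(i, c.severity, None, Surface.UNDETERMINED, reason="no overlapping tooth")
            )
            continue
        surface = determine_surface(c, by_fdi[fdi], side)
        reason = None
        if surface is Surface.UNDETERMINED:
            reason = "side unknown" if side is Side.UNKNOWN else "lesion centered on tooth midline"
        out.append(Diagnosis(i, c.severity, fdi, surface, reason=reason))
    return out
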
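"""Detection/segmentation metric protocol: IoU matching, P/R/F1, AP, macro mAP.

Matching follows the standard detection-evaluation convention: predictions
below the confidence threshold are discarded; the survivors are processed in
descending confidence and greedily matched, class-exclusively, to the
unmatched same-class ground truth of highest IoU; a match counts as a true
positive iff that IoU reaches the IoU threshold, otherwise the prediction is
a false positive. Ground truths left unmatched are false negatives.

Average precision uses all-point interpolation: the precision-recall curve is
swept over descending confidence (confidence threshold 0), the precision
envelope is made monotone non-increasing, and AP is the area under the
enveloped curve. Macro ("overall") precision, recall and F1 are unweighted
class means, and mAP = (1/C) * sum of per-class APs over the C classes.

Matching can use box IoU or rasterized mask IoU (``iou_kind``); boxes suit
object-detection output, masks suit instance segmentation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .assignment import Diagnosis, Surface
from .scene import (
    Box,
    CariesDetection,
    Frame,
    Severity,
    box_iou,
    mask_iou,
)

IOU_KINDS = ("box", "mask")


def _pair_iou(p: CariesDetection, g: CariesDetection, kind: str, frame: Optional[Frame]) -> float:
    if kind == "box":
        return box_iou(p.box, g.box)
    if kind == "mask":
        if frame is None:
            raise ValueError("mask IoU requires a frame for rasterization")
        return mask_iou(p.polygon, g.polygon, frame)
    raise ValueError(f"unknown iou_kind {kind!r}; expected one of {IOU_KINDS}")


def _check_thresholds(iou_thr: float, conf_thr: float) -> None:
    if not 0.0 <= iou_thr <= 1.0:
        raise ValueError(f"iou_thr {iou_thr} outside [0, 1]")
    if not 0.0 <= conf_thr <= 1.0:
        raise ValueError(f"conf_thr {conf_thr} outside [0, 1]")


@dataclass(frozen=True)
class MatchedPair:
    pred_index: int
    gt_index: int
    iou: float


@dataclass
class MatchResult:
    """Per-class TP/FP/FN bookkeeping for one set of detections."""

    tp: dict[Severity, int] = field(default_factory=dict)
    fp: dict[Severity, int] = field(default_factory=dict)
    fn: dict[Severity, int] = field(default_factory=dict)
    matches: list[MatchedPair] = field(default_factory=list)

    def add(self, other: "MatchResult") -> None:
        for cls in Severity:
            self.tp[cls] = self.tp.get(cls, 0) + other.tp.get(cls, 0)
            self.fp[cls] = self.fp.get(cls, 0) + other.fp.get(cls, 0)
            self.fn[cls] = self.fn.get(cls, 0) + other.fn.get(cls, 0)


def match_detections(
    preds: Sequence[CariesDetection],
    gts: Sequence[CariesDetection],
    iou_thr: float = 0.5,
    conf_thr: float = 0.25,
    iou_kind: str = "box",
    frame: Optional[Frame] = None,
) -> MatchResult:
    """Greedy class-exclusive matching of predictions to ground truths."""
    _check_thresholds(iou_thr, conf_thr)
    result = MatchResult(
        tp={c: 0 for c in Severity}, fp={c: 0 for c in Severity}, fn={c: 0 for c in Severity}
    )
    kept = [(i, p) for i, p in enumerate(preds) if p.confidence >= conf_thr]
    kept.sort(key=lambda ip: (-ip[1].confidence, ip[0]))
    gt_taken = [False] * len(gts)
    for pi, p in kept:
        best_iou, best_gi = 0.0, -1
        for gi, g in enumerate(gts):
            if gt_taken[gi] or g.severity is not p.severity:
                continue
            iou = _pair_iou(p, g, iou_kind, frame)
            if iou > best_iou:
                best_iou, best_gi = iou, gi
        if best_gi >= 0 and best_iou >= iou_thr and best_iou > 0.0:
            gt_taken[best_gi] = True
            result.tp[p.severity] += 1
            result.matches.append(MatchedPair(pi, best_gi, best_iou))
        else:
            result.fp[p.severity] += 1
    for gi, g in enumerate(gts):
        if not gt_taken[gi]:
            result.fn[g.severity] += 1
    return result


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def precision_recall_f1(m: MatchResult, cls: Severity) -> tuple[float, float, float]:
    """Precision, recall and F1 for one class; 0/0 ratios are reported as 0."""
    tp = m.tp.get(cls, 0)
    fp = m.fp.get(cls, 0)
    fn = m.fn.get(cls, 0)
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    return p, r, f1_score(p, r)


def macro_average(values: Iterable[float]) -> float:
    """Unweighted mean over classes (the 'overall performance' aggregation)."""
    vals = list(values)
    if not vals:
        return 0.0
    return float(np.mean(vals))


def mean_average_precision(aps: Iterable[float]) -> float:
    """mAP = (1/C) * sum of per-class average precisions."""
    return macro_average(aps)


def _ap_from_ranked(flags: Sequence[bool], n_gt: int) -> float:
    """Area under the monotone precision envelope of a ranked TP/FP sequence."""
    if n_gt == 0:
        raise ValueError("AP undefined with zero ground truths")
    if not flags:
        return 0.0
    tp_cum = np.cumsum(np.asarray(flags, dtype=float))
    ranks = np.arange(1, len(flags) + 1, dtype=float)
    precision = tp_cum / ranks
    recall = tp_cum / n_gt
    # monotone non-increasing precision envelope, then sum rectangle areas
    env = np.maximum.accumulate(precision[::-1])[::-1]
    prev_r = 0.0
    ap = 0.0
    for r, p in zip(recall, env):
        ap += (r - prev_r) * p
        prev_r = r
    return float(ap)


def _ranked_flags(
    image_pairs: Sequence[tuple[Sequence[CariesDetection], Sequence[CariesDetection], Optional[Frame]]],
    cls: Optional[Severity],
    iou_thr: float,
    iou_kind: str,
) -> tuple[list[bool], int]:
    """Pool all images: rank predictions globally, match within each image."""
    entries: list[tuple[float, int, int, bool]] = []  # (-conf, img, idx, is_tp)
    n_gt = 0
    for img_idx, (preds, gts, frame) in enumerate(image_pairs):
        sel_gts = [g for g in gts if cls is None or g.severity is cls]
        n_gt += len(sel_gts)
        sel_preds = [
            (i, p) for i, p in enumerate(preds) if cls is None or p.severity is cls
        ]
        sel_preds.sort(key=lambda ip: (-ip[1].confidence, ip[0]))
        taken = [False] * len(sel_gts)
        for pi, p in sel_preds:
            best_iou, best_gi = 0.0, -1
            for gi, g in enumerate(sel_gts):
                if taken[gi] or (cls is None and g.severity is not p.severity):
                    continue
                iou = _pair_iou(p, g, iou_kind, frame)
                if iou > best_iou:
                    best_iou, best_gi = iou, gi
            is_tp = best_gi >= 0 and best_iou >= iou_thr and best_iou > 0.0
            if is_tp:
                taken[best_gi] = True
            entries.append((-p.confidence, img_idx, pi, is_tp))
    entries.sort()
    return [e[3] for e in entries], n_gt


def average_precision(
    preds: Sequence[CariesDetection],
    gts: Sequence[CariesDetection],
    iou_thr: float = 0.5,
    iou_kind: str = "box",
    frame: Optional[Frame] = None,
    cls: Optional[Severity] = None,
) -> float:
    """All-point-interpolated AP for one image (confidence threshold 0).

    With ``cls`` given, predictions and ground truths are restricted to that
    class; otherwise all detections are pooled but matching stays
    class-exclusive.
    """
    _check_thresholds(iou_thr, 0.0)
    flags, n_gt = _ranked_flags([(preds, gts, frame)], cls, iou_thr, iou_kind)
    return _ap_from_ranked(flags, n_gt)


@dataclass(frozen=True)
class ClassMetrics:
    precision: float
    recall: float
    f1: float
    ap: Optional[float]
    tp: int
    fp: int
    fn: int


@dataclass(frozen=True)
class MetricsReport:
    """Per-class and macro metrics at one (IoU, confidence) operating point."""

    per_class: Mapping[Severity, ClassMetrics]
    precision: float
    recall: float
    f1: float
    map: float
    iou_thr: float
    conf_thr: float
    iou_kind: str

    def to_dict(self) -> dict:
        return {
            "iou_thr": self.iou_thr,
            "conf_thr": self.conf_thr,
            "iou_kind": self.iou_kind,
            "classes": {
                c.label: {
                    "precision": m.precision,
                    "recall": m.recall,
                    "f1": m.f1,
                    "ap": m.ap,
                    "tp": m.tp,
                    "fp": m.fp,
                    "fn": m.fn,
                }
                for c, m in self.per_class.items()
            },
            "macro": {
                "precision": self.precision,
                "recall": self.recall,
                "f1": self.f1,
                "mAP": self.map,
            },
        }


def _as_image_pairs(pred_set, gt_set):
    """Pair prediction and ground-truth scenes by image_id."""
    pred_by_id = {s.image_id: s for s in pred_set.scenes}
    gt_by_id = {s.image_id: s for s in gt_set.scenes}
    if set(pred_by_id) != set(gt_by_id):
        missing = set(gt_by_id) ^ set(pred_by_id)
        raise ValueError(f"prediction/ground-truth image_id mismatch: {sorted(missing)[:5]}")
    pairs = []
    for image_id in sorted(gt_by_id):
        g = gt_by_id[image_id]
        pairs.append((pred_by_id[image_id].caries, g.caries, g.frame))
    return pairs


def evaluate(
    pred_set,
    gt_set,
    iou_thr: float = 0.5,
    conf_thr: float = 0.25,
    iou_kind: str = "box",
) -> MetricsReport:
    """Pooled per-class metrics over all images of two AnnotationSets.

    TP/FP/FN are accumulated in a single confusion over all images (not
    averaged per image); AP pools the globally ranked predictions with
    confidence threshold 0. Classes absent from the ground truth have
    undefined AP and are excluded from the macro mAP with a warning.
    """
    _check_thresholds(iou_thr, conf_thr)
    pairs = _as_image_pairs(pred_set, gt_set)
    total = MatchResult(
        tp={c: 0 for c in Severity}, fp={c: 0 for c in Severity}, fn={c: 0 for c in Severity}
    )
    for preds, gts, frame in pairs:
        total.add(match_detections(preds, gts, iou_thr, conf_thr, iou_kind, frame))

    per_class: dict[Severity, ClassMetrics] = {}
    aps: list[float] = []
    for cls in Severity:
        p, r, f1 = precision_recall_f1(total, cls)
        flags, n_gt = _ranked_flags(pairs, cls, iou_thr, iou_kind)
        if n_gt == 0:
            warnings.warn(f"no ground-truth instances of class {cls.label}; AP undefined")
            ap = None
        else:
            ap = _ap_from_ranked(flags, n_gt)
            aps.append(ap)
        per_class[cls] = ClassMetrics(
            p, r, f1, ap, total.tp[cls], total.fp[cls], total.fn[cls]
        )
    return MetricsReport(
        per_class=per_class,
        precision=macro_average(m.precision for m in per_class.values()),
        recall=macro_average(m.recall for m in per_class.values()),
        f1=macro_average(m.f1 for m in per_class.values()),
        map=mean_average_precision(aps),
        iou_thr=iou_thr,
        conf_thr=conf_thr,
        iou_kind=iou_kind,
    )


def threshold_sweep(
    pred_set,
    gt_set,
    iou_list: Sequence[float] = (0.5, 0.75),
    conf_list: Sequence[float] = (0.001, 0.25, 0.5),
    iou_kind: str = "box",
) -> dict[tuple[float, float], MetricsReport]:
    """One MetricsReport per (IoU threshold, confidence threshold) pair."""
    if not iou_list or not conf_list:
        raise ValueError("threshold lists must be non-empty")
    return {
        (iou, conf): evaluate(pred_set, gt_set, iou, conf, iou_kind)
        for iou in iou_list
        for conf in conf_list
    }


@dataclass(frozen=True)
class DiagnosisTally:
    """Diagnosis-comparison counts over matched lesion instances.

    Mirrors a clinical reader-study tally: how many lesions were detected at
    all, how many had the complete diagnosis right, and how many got each
    component (severity, tooth, surface) right.
    """

    total_gt: int
    detected: int
    fully_correct: int
    severity_correct: int
    tooth_correct: int
    surface_correct: int


def compare_diagnoses(
    pred: Mapping[str, tuple[Sequence[CariesDetection], Sequence[Diagnosis]]],
    gt: Mapping[str, tuple[Sequence[CariesDetection], Sequence[Diagnosis]]],
    iou_thr: float = 0.5,
) -> DiagnosisTally:
    """Tally agreement between predicted and reference per-lesion diagnoses.

    Lesions are put in correspondence per image by greedy box-IoU matching
    (highest IoU first, each lesion used at most once, IoU >= iou_thr).
    """
    total_gt = detected = fully = sev = tooth = surf = 0
    for image_id in sorted(gt):
        gt_caries, gt_diags = gt[image_id]
        total_gt += len(gt_caries)
        if image_id not in pred:
            continue
        pr_caries, pr_diags = pred[image_id]
        cand = [
            (box_iou(pc.box, gc.box), pi, gi)
            for pi, pc in enumerate(pr_caries)
            for gi, gc in enumerate(gt_caries)
        ]
        cand = [c for c in cand if c[0] >= iou_thr]
        cand.sort(key=lambda c: (-c[0], c[1], c[2]))
        p_used: set[int] = set()
        g_used: set[int] = set()
        for iou, pi, gi in cand:
            if pi in p_used or gi in g_used:
                continue
            p_used.add(pi)
            g_used.add(gi)
            detected += 1
            pd = next(d for d in pr_diags if d.caries_index == pi)
            gd = next(d for d in gt_diags if d.caries_index == gi)
            ok_sev = pd.severity is gd.severity
            ok_tooth = pd.tooth == gd.tooth
            ok_surf = pd.surface is gd.surface
            sev += ok_sev
            tooth += ok_tooth
            surf += ok_surf
            fully += ok_sev and ok_tooth and ok_surf
    return DiagnosisTally(total_gt, detected, fully, sev, tooth, surf)
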
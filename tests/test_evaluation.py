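"""IoU matching, precision/recall/F1, average precision and diagnosis tallies."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bitewing.annotation_io import AnnotationSet
from bitewing.assignment import diagnose_scene
from bitewing.evaluation import (
    MatchResult,
    average_precision,
    compare_diagnoses,
    evaluate,
    f1_score,
    match_detections,
    mean_average_precision,
    precision_recall_f1,
    threshold_sweep,
)
from bitewing.scene import Box, Frame, Scene, Severity, box_iou
from bitewing.synthetic import (
    ConfidenceModel,
    PerturbationConfig,
    SceneGenConfig,
    generate_scene,
    mock_detect,
)
from conftest import rect_caries


def det(x0, y0, x1, y1, sev=Severity.RA, conf=1.0):
    return rect_caries(x0, y0, x1, y1, sev, conf)


class TestMatchDetections:
    def test_identity_predictions(self):
        gts = [det(0, 0, 10, 10), det(50, 0, 60, 10, Severity.RB)]
        m = match_detections(gts, gts, 0.5, 0.25)
        assert m.tp[Severity.RA] == 1 and m.tp[Severity.RB] == 1
        assert sum(m.fp.values()) == 0 and sum(m.fn.values()) == 0

    def test_no_predictions(self):
        gts = [det(0, 0, 10, 10), det(50, 0, 60, 10)]
        m = match_detections([], gts, 0.5, 0.25)
        assert m.fn[Severity.RA] == 2

    def test_below_iou_threshold_counts_fp_and_fn(self):
        gt = det(0, 0, 10, 10)
        pred = det(0, 0, 10, 4)  # IoU = 40/100 = 0.4
        assert box_iou(pred.box, gt.box) == pytest.approx(0.4)
        m = match_detections([pred], [gt], 0.5, 0.25)
        assert (m.tp[Severity.RA], m.fp[Severity.RA], m.fn[Severity.RA]) == (0, 1, 1)

    def test_confidence_filter_discards(self):
        gt = det(0, 0, 10, 10)
        pred = det(0, 0, 10, 10, conf=0.1)
        m = match_detections([pred], [gt], 0.5, 0.25)
        assert m.fn[Severity.RA] == 1 and m.fp[Severity.RA] == 0

    def test_wrong_class_overlap_is_fp_for_predicted_class(self):
        gt = det(0, 0, 10, 10, Severity.RA)
        pred = det(0, 0, 10, 10, Severity.RB)
        m = match_detections([pred], [gt], 0.5, 0.25)
        assert m.fp[Severity.RB] == 1 and m.fn[Severity.RA] == 1

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            match_detections([], [], iou_thr=1.5)

    def test_greedy_equals_exhaustive_on_small_instances(self):
        """When every IoU is either >= threshold or 0, greedy matching attains
        the maximum-matching TP count on instances up to 4x4."""
        rng = np.random.default_rng(12)
        slots = [(60 * i, 60 * j) for i in range(3) for j in range(3)]
        for _ in range(200):
            n_gt = int(rng.integers(1, 5))
            n_pr = int(rng.integers(0, 5))
            gt_slots = rng.choice(len(slots), size=n_gt, replace=False)
            gts = [
                det(*slots[k], slots[k][0] + 20, slots[k][1] + 20,
                    Severity(int(rng.integers(0, 3))))
                for k in gt_slots
            ]
            preds = []
            for _ in range(n_pr):
                k = int(rng.integers(0, len(slots)))
                preds.append(
                    det(*slots[k], slots[k][0] + 20, slots[k][1] + 20,
                        Severity(int(rng.integers(0, 3))), float(rng.random()))
                )
            m = match_detections(preds, gts, 0.5, 0.0)
            greedy_tp = sum(m.tp.values())

            # brute-force maximum matching over injective assignments
            pairs = [
                (pi, gi)
                for pi, p in enumerate(preds)
                for gi, g in enumerate(gts)
                if p.severity is g.severity and box_iou(p.box, g.box) >= 0.5
            ]
            best = 0
            for r in range(len(pairs), 0, -1):
                for combo in itertools.combinations(pairs, r):
                    ps = [c[0] for c in combo]
                    gs = [c[1] for c in combo]
                    if len(set(ps)) == r and len(set(gs)) == r:
                        best = r
                        break
                if best:
                    break
            assert greedy_tp == best


class TestPrecisionRecallF1:
    @pytest.mark.parametrize(
        "p, r, expected",
        [(0.796, 0.882, 0.837), (0.928, 0.816, 0.868), (0.808, 0.894, 0.849)],
    )
    def test_f1_from_published_operating_points(self, p, r, expected):
        assert round(f1_score(p, r), 3) == expected

    def test_empty_convention(self):
        m = MatchResult(tp={Severity.RA: 0}, fp={Severity.RA: 0}, fn={Severity.RA: 0})
        assert precision_recall_f1(m, Severity.RA) == (0.0, 0.0, 0.0)

    def test_counts(self):
        m = MatchResult(tp={Severity.RA: 3}, fp={Severity.RA: 1}, fn={Severity.RA: 2})
        p, r, f1 = precision_recall_f1(m, Severity.RA)
        assert (p, r) == (0.75, 0.6)
        assert f1 == pytest.approx(2 * 0.75 * 0.6 / 1.35)

    @given(st.floats(0, 1), st.floats(0, 1))
    def test_f1_bounds(self, p, r):
        f1 = f1_score(p, r)
        assert 0.0 <= f1 <= (p + r) / 2 + 1e-12
        assert (f1 == 0.0) == (p * r == 0.0)


class TestAveragePrecision:
    def test_single_correct_prediction(self):
        gt = det(0, 0, 10, 10)
        assert average_precision([det(0, 0, 10, 10, conf=0.9)], [gt]) == 1.0

    def test_high_confidence_fp_then_tp(self):
        gt = det(0, 0, 10, 10)
        preds = [det(200, 200, 210, 210, conf=0.9), det(0, 0, 10, 10, conf=0.5)]
        # PR points: (r=0, p=0) then (r=1, p=0.5) -> all-point AP = 0.5
        assert average_precision(preds, [gt]) == pytest.approx(0.5)

    def test_all_false_positives(self):
        gt = det(0, 0, 10, 10)
        preds = [det(200, 200, 210, 210, conf=c) for c in (0.9, 0.5)]
        assert average_precision(preds, [gt]) == 0.0

    def test_zero_ground_truths_raise(self):
        with pytest.raises(ValueError):
            average_precision([det(0, 0, 10, 10)], [])

    def test_invariant_to_confidence_rescaling(self):
        rng = np.random.default_rng(3)
        gts = [det(40 * i, 0, 40 * i + 20, 20) for i in range(4)]
        preds = [
            det(40 * i + dx, 0, 40 * i + 20 + dx, 20, conf=float(rng.random()))
            for i, dx in zip(range(4), (1, 3, 25, 2))
        ]
        base = average_precision(preds, gts)
        scaled = [
            det(p.box.x_min, p.box.y_min, p.box.x_max, p.box.y_max,
                p.severity, p.confidence * 0.5)
            for p in preds
        ]
        assert average_precision(scaled, gts) == base


def scenes_and_mocks(seed, n=8, pcfg=None):
    cfg = SceneGenConfig(seed=seed, lesion_rate=0.8)
    pcfg = pcfg or PerturbationConfig(seed=seed)
    gt_scenes, pred_scenes = [], []
    for i in range(n):
        s, _, _ = generate_scene(cfg, i)
        gt_scenes.append(s)
        pred_scenes.append(Scene(s.image_id, s.frame, (), tuple(mock_detect(s, pcfg))))
    return AnnotationSet(pred_scenes), AnnotationSet(gt_scenes)


class TestEvaluate:
    @pytest.mark.parametrize(
        "values, expected",
        [((0.864, 0.887, 0.912), 0.888), ((0.837, 0.868, 0.849), 0.851)],
    )
    def test_macro_aggregation_of_published_values(self, values, expected):
        assert round(mean_average_precision(values), 3) == expected

    def test_perfect_predictions_score_one(self):
        pcfg = PerturbationConfig(
            box_jitter_sd=0, vertex_jitter_sd=0, miss_rate=0, spurious_rate=0,
            class_confusion=tuple(tuple(1.0 if i == j else 0.0 for j in range(3)) for i in range(3)),
            conf_model=ConfidenceModel(true_a=1, true_b=0),
        )
        pred, gt = scenes_and_mocks(seed=4, pcfg=pcfg)
        rep = evaluate(pred, gt)
        assert rep.precision == rep.recall == rep.f1 == rep.map == 1.0

    def test_map_is_mean_of_class_aps(self):
        pred, gt = scenes_and_mocks(seed=5)
        rep = evaluate(pred, gt)
        aps = [m.ap for m in rep.per_class.values() if m.ap is not None]
        assert rep.map == np.mean(aps)

    def test_image_id_mismatch(self):
        pred, gt = scenes_and_mocks(seed=6, n=2)
        renamed = AnnotationSet(
            [Scene("other", s.frame, s.teeth, s.caries) for s in pred.scenes[:1]]
        )
        with pytest.raises(ValueError, match="mismatch"):
            evaluate(renamed, gt)


class TestThresholdSweep:
    def test_default_grid_has_six_reports(self):
        pred, gt = scenes_and_mocks(seed=7, n=4)
        reports = threshold_sweep(pred, gt)
        assert len(reports) == 6
        assert set(reports) == {(i, c) for i in (0.5, 0.75) for c in (0.001, 0.25, 0.5)}

    @pytest.mark.parametrize("seed", range(10))
    def test_recall_monotone_in_confidence_and_ap_in_iou(self, seed):
        pred, gt = scenes_and_mocks(seed=seed, n=5)
        reports = threshold_sweep(pred, gt)
        for iou in (0.5, 0.75):
            r_low = reports[(iou, 0.001)]
            r_mid = reports[(iou, 0.25)]
            r_high = reports[(iou, 0.5)]
            for cls in Severity:
                rec = [rep.per_class[cls].recall for rep in (r_low, r_mid, r_high)]
                assert rec[0] >= rec[1] >= rec[2]
        for conf in (0.001, 0.25, 0.5):
            for cls in Severity:
                ap50 = reports[(0.5, conf)].per_class[cls].ap
                ap75 = reports[(0.75, conf)].per_class[cls].ap
                if ap50 is not None and ap75 is not None:
                    assert ap75 <= ap50 + 1e-12

    def test_empty_grid_rejected(self):
        pred, gt = scenes_and_mocks(seed=8, n=2)
        with pytest.raises(ValueError):
            threshold_sweep(pred, gt, iou_list=[])


class TestCompareDiagnoses:
    @staticmethod
    def diagnosed(scene):
        return scene.caries, diagnose_scene(scene)

    def test_identical_diagnoses(self, gen_scenes):
        data = {s.image_id: self.diagnosed(s) for s, _, _ in gen_scenes[:10]}
        n = sum(len(c) for c, _ in data.values())
        tally = compare_diagnoses(data, data)
        assert (
            tally.detected, tally.fully_correct, tally.severity_correct,
            tally.tooth_correct, tally.surface_correct,
        ) == (n, n, n, n, n)

    def test_single_wrong_severity(self, gen_scenes):
        scene = next(s for s, _, _ in gen_scenes if len(s.caries) >= 1)
        gt = {scene.image_id: self.diagnosed(scene)}
        caries, diags = self.diagnosed(scene)
        wrong_sev = Severity((caries[0].severity.class_id + 1) % 3)
        pred_caries = (
            rect_caries(
                caries[0].box.x_min, caries[0].box.y_min,
                caries[0].box.x_max, caries[0].box.y_max, wrong_sev,
            ),
            *caries[1:],
        )
        pred_scene = Scene(scene.image_id, scene.frame, scene.teeth, pred_caries)
        pred = {scene.image_id: (pred_caries, diagnose_scene(pred_scene))}
        n = len(caries)
        tally = compare_diagnoses(pred, gt)
        assert tally.detected == n
        assert tally.severity_correct == n - 1
        assert tally.fully_correct == n - 1
        assert tally.tooth_correct == n
        assert tally.surface_correct == n

    def test_empty_predictions(self, gen_scenes):
        gt = {s.image_id: self.diagnosed(s) for s, _, _ in gen_scenes[:5]}
        pred = {image_id: ((), ()) for image_id in gt}
        tally = compare_diagnoses(pred, gt)
        assert tally.detected == 0
        assert tally.fully_correct == 0
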
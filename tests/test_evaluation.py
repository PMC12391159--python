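import itertools

import numpy as np
import pytest

from hemovision.evaluation import (
    ConfusionMatrix,
    ClassMetrics,
    Outcome,
    aggregate_folds,
    confusion_from_matches,
    iou,
    load_confusion_csv,
    match_detections,
    metrics_from_confusion,
    round_half_up,
    save_confusion_csv,
    stratified_split,
)
from hemovision.fixtures import load_reference_table
from hemovision.yolo_io import Annotation, ClassScheme, Detection, LabeledImage, NormBox


def box_px(x0, y0, x1, y1, scale=100):
    return NormBox.from_pixels(x0, y0, x1, y1, scale, scale)


def shapely_iou(a: NormBox, b: NormBox):
    """Independent IoU oracle through shapely's polygon-clipping engine."""
    from shapely.geometry import box as shapely_box

    pa = shapely_box(a.x0, a.y0, a.x1, a.y1)
    pb = shapely_box(b.x0, b.y0, b.x1, b.y1)
    return pa.intersection(pb).area / pa.union(pb).area


def rasterized_iou(a: NormBox, b: NormBox, res=2000):
    """Coarse brute-force oracle: rasterize both boxes on a pixel grid."""
    grid_a = np.zeros((res, res), dtype=bool)
    grid_b = np.zeros((res, res), dtype=bool)
    for g, bx in ((grid_a, a), (grid_b, b)):
        g[round(bx.y0 * res): round(bx.y1 * res),
          round(bx.x0 * res): round(bx.x1 * res)] = True
    inter = np.logical_and(grid_a, grid_b).sum()
    union = np.logical_or(grid_a, grid_b).sum()
    return inter / union


class TestIoU:
    def test_identical_boxes(self):
        b = NormBox(0.5, 0.5, 0.2, 0.2)
        assert iou(b, b) == 1.0

    def test_disjoint_boxes(self):
        assert iou(NormBox(0.2, 0.2, 0.1, 0.1), NormBox(0.8, 0.8, 0.1, 0.1)) == 0.0

    def test_corner_overlap_one_seventh(self):
        # [0,2]x[0,2] and [1,3]x[1,3]: intersection 1, union 7
        a = box_px(0, 0, 2, 2)
        b = box_px(1, 1, 3, 3)
        assert iou(a, b) == pytest.approx(1 / 7, abs=1e-12)

    def test_zero_area_box_raises(self):
        good = NormBox(0.5, 0.5, 0.2, 0.2)
        bad = NormBox.__new__(NormBox)
        object.__setattr__(bad, "cx", 0.5)
        object.__setattr__(bad, "cy", 0.5)
        object.__setattr__(bad, "w", 0.0)
        object.__setattr__(bad, "h", 0.1)
        with pytest.raises(ValueError):
            iou(good, bad)

    def test_against_independent_oracles(self):
        rng = np.random.default_rng(17)
        for i in range(200):
            boxes = []
            for _ in range(2):
                w, h = rng.uniform(0.05, 0.5, size=2)
                boxes.append(NormBox(float(rng.uniform(w / 2, 1 - w / 2)),
                                     float(rng.uniform(h / 2, 1 - h / 2)),
                                     float(w), float(h)))
            assert iou(*boxes) == pytest.approx(shapely_iou(*boxes), abs=1e-9)
            if i < 20:  # coarse pixel-counting sanity check
                got = iou(*boxes)
                ras = rasterized_iou(*boxes)
                assert got == pytest.approx(ras, abs=5e-3 + 0.05 * ras)


def exhaustive_match(annotations, detections, thr=0.75):
    """Oracle: replay the greedy claiming rule by explicit enumeration of
    detections in confidence order, checking every unmatched annotation."""
    order = sorted(
        range(len(detections)),
        key=lambda j: (
            -detections[j].confidence,
            -max((iou(detections[j].box, a.box) for a in annotations), default=0.0),
            j,
        ),
    )
    claimed = {}
    outcomes = {}
    for j in order:
        ious = [(iou(detections[j].box, a.box), i) for i, a in enumerate(annotations)]
        best = max((v for v, _ in ious), default=0.0)
        if best < thr:
            outcomes[j] = Outcome.FP_SPURIOUS
            continue
        avail = [(v, -i) for v, i in ious if v >= thr and i not in claimed.values()]
        if not avail:
            outcomes[j] = Outcome.FP_DUPLICATE
            continue
        v, negi = max(avail)
        claimed[j] = -negi
        outcomes[j] = (
            Outcome.TP
            if detections[j].class_id == annotations[-negi].class_id
            else Outcome.FP_WRONG_CLASS
        )
    return claimed, outcomes


def random_scene(rng, max_boxes=6):
    annotations = []
    for _ in range(int(rng.integers(0, max_boxes + 1))):
        w, h = rng.uniform(0.05, 0.3, size=2)
        annotations.append(Annotation(
            int(rng.integers(0, 3)),
            NormBox(float(rng.uniform(w / 2, 1 - w / 2)),
                    float(rng.uniform(h / 2, 1 - h / 2)), float(w), float(h)),
        ))
    detections = []
    for a in annotations:
        if rng.random() < 0.8:  # jittered copy of a ground-truth box
            dx, dy = rng.uniform(-0.02, 0.02, size=2)
            s = float(rng.uniform(0.9, 1.1))
            w = min(a.box.w * s, 0.95)
            h = min(a.box.h * s, 0.95)
            cx = float(np.clip(a.box.cx + dx, w / 2, 1 - w / 2))
            cy = float(np.clip(a.box.cy + dy, h / 2, 1 - h / 2))
            detections.append(Detection(
                int(rng.integers(0, 3)) if rng.random() < 0.3 else a.class_id,
                NormBox(cx, cy, float(w), float(h)), float(rng.uniform(0.1, 0.99))))
    for _ in range(int(rng.integers(0, 3))):  # noise detections
        w, h = rng.uniform(0.05, 0.2, size=2)
        detections.append(Detection(
            int(rng.integers(0, 3)),
            NormBox(float(rng.uniform(w / 2, 1 - w / 2)),
                    float(rng.uniform(h / 2, 1 - h / 2)), float(w), float(h)),
            float(rng.uniform(0.1, 0.99))))
    return annotations, detections


class TestMatching:
    def test_single_tp(self):
        ann = [Annotation(0, box_px(10, 10, 30, 30))]
        det = [Detection(0, box_px(10, 12, 30, 32), 0.9)]  # IoU ~0.82
        mr = match_detections(ann, det)
        assert mr.outcomes == [Outcome.TP]
        assert mr.n_non_detected == 0

    def test_wrong_class_fills_confusion_cell(self):
        scheme = ClassScheme(["echinocyte", "erythrocyte"])
        ann = [Annotation(1, box_px(10, 10, 30, 30))]
        det = [Detection(0, box_px(10, 11, 30, 31), 0.9)]  # high IoU, wrong class
        mr = match_detections(ann, det)
        assert mr.outcomes == [Outcome.FP_WRONG_CLASS]
        cm = confusion_from_matches([mr], scheme)
        assert cm.counts[1, 0] == 1  # erythrocyte row, echinocyte column
        assert cm.counts.sum() == 1

    def test_below_threshold_is_spurious_and_annotation_undetected(self):
        ann = [Annotation(0, box_px(10, 10, 30, 30))]
        det = [Detection(0, box_px(22, 22, 42, 42), 0.9)]
        mr = match_detections(ann, det)
        assert mr.outcomes == [Outcome.FP_SPURIOUS]
        assert mr.n_non_detected == 1

    def test_duplicate_detection_flagged(self):
        ann = [Annotation(0, box_px(10, 10, 30, 30))]
        det = [
            Detection(0, box_px(10, 10, 30, 30), 0.95),
            Detection(0, box_px(11, 10, 31, 30), 0.80),
        ]
        mr = match_detections(ann, det)
        assert mr.outcomes == [Outcome.TP, Outcome.FP_DUPLICATE]

    def test_threshold_is_inclusive(self):
        # construct IoU exactly 0.75: [0,100]x[0,75] vs [0,100]x[0,100]
        ann = [Annotation(0, box_px(0, 0, 100, 100))]
        det = [Detection(0, box_px(0, 0, 100, 75), 0.9)]
        mr = match_detections(ann, det, iou_threshold=0.75)
        assert mr.outcomes == [Outcome.TP]

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            match_detections([], [], iou_threshold=0.0)

    def test_greedy_equals_exhaustive_on_random_scenes(self):
        rng = np.random.default_rng(23)
        for _ in range(200):
            ann, det = random_scene(rng)
            mr = match_detections(ann, det)
            claimed, outcomes = exhaustive_match(ann, det)
            got_claims = {
                j: i for i, j in enumerate(mr.matched_detection) if j is not None
            }
            assert got_claims == claimed
            assert dict(enumerate(mr.outcomes)) == outcomes

    def test_conservation_per_class(self):
        rng = np.random.default_rng(29)
        scheme = ClassScheme(["a", "b", "c"])
        scenes = [random_scene(rng) for _ in range(50)]
        mrs = [match_detections(a, d) for a, d in scenes]
        cm = confusion_from_matches(mrs, scheme)
        gt_counts = np.zeros(3, dtype=int)
        for a, _ in scenes:
            for ann in a:
                gt_counts[ann.class_id] += 1
        assert np.array_equal(cm.row_totals(), gt_counts)


class TestConfusionMatrix:
    def test_perfect_detector_diagonal(self):
        scheme = ClassScheme(["a", "b"])
        ann = [Annotation(0, box_px(10, 10, 30, 30)), Annotation(1, box_px(50, 50, 80, 80))]
        det = [Detection(0, box_px(10, 10, 30, 30), 0.9),
               Detection(1, box_px(50, 50, 80, 80), 0.9)]
        cm = confusion_from_matches([match_detections(ann, det)], scheme)
        assert np.array_equal(cm.counts, [[1, 0, 0], [0, 1, 0]])
        assert cm.spurious.sum() == 0

    def test_silent_detector_all_non_detected(self):
        scheme = ClassScheme(["a", "b"])
        ann = [Annotation(0, box_px(10, 10, 30, 30)), Annotation(1, box_px(50, 50, 80, 80))]
        cm = confusion_from_matches([match_detections(ann, [])], scheme)
        assert np.array_equal(cm.counts, [[0, 0, 1], [0, 0, 1]])

    def test_programmed_error_rates_recovered(self):
        # a simulated detector with known flip and miss rates: the confusion
        # matrix must agree with the programmed multinomial within sampling
        # error
        rng = np.random.default_rng(31)
        scheme = ClassScheme(["a", "b"])
        flip, miss = 0.15, 0.10
        n = 4000
        mrs = []
        for _ in range(n):
            ann = [Annotation(0, box_px(20, 20, 60, 60))]
            u = rng.random()
            if u < miss:
                det = []
            else:
                cls = 1 if u < miss + flip else 0
                det = [Detection(cls, box_px(20, 20, 60, 60), 0.9)]
            mrs.append(match_detections(ann, det))
        cm = confusion_from_matches(mrs, scheme)
        assert cm.counts[0, 1] / n == pytest.approx(flip, abs=3 * np.sqrt(flip * (1 - flip) / n))
        assert cm.counts[0, 2] / n == pytest.approx(miss, abs=3 * np.sqrt(miss * (1 - miss) / n))

    def test_merged_scheme_recall_never_below_worst_submerged(self):
        cm6 = load_reference_table("four_class")
        cm3 = cm6.merged({0: 0, 1: 0, 2: 1, 3: 2}, ["red cell", "leukocyte", "platelet"])
        m6 = metrics_from_confusion(cm6)
        m3 = metrics_from_confusion(cm3)
        assert m3["red cell"].recall >= min(m6["echinocyte"].recall, m6["erythrocyte"].recall)

    def test_csv_roundtrip(self, tmp_path):
        cm = load_reference_table("two_class_optimised")
        p = tmp_path / "cm.csv"
        save_confusion_csv(cm, p)
        back = load_confusion_csv(p)
        assert back.class_names == cm.class_names
        assert np.array_equal(back.counts, cm.counts)


class TestMetricsFromConfusion:
    def test_reference_two_class_optimised_percentages(self):
        # 81/15/2 and 9/232/1 with zero spurious
        m = metrics_from_confusion(load_reference_table("two_class_optimised"))
        pct = {k: v.as_percent() for k, v in m.items()}
        assert pct["echinocyte"]["precision"] == 90.0
        assert pct["erythrocyte"]["precision"] == 93.9
        assert pct["erythrocyte"]["recall"] == 95.9
        assert pct["echinocyte"]["f1"] == 86.2

    def test_reference_two_class_initial_error_pattern(self):
        cm = load_reference_table("two_class_initial")
        row_ech = cm.counts[0]
        row_ery = cm.counts[1]
        assert round_half_up(100 * row_ech[0] / row_ech.sum(), 1) == 77.0
        assert round_half_up(100 * row_ech[1] / row_ech.sum(), 1) == 12.5
        assert round_half_up(100 * row_ery[1] / row_ery.sum(), 1) == 90.2
        assert round_half_up(100 * row_ery[0] / row_ery.sum(), 1) == 7.5
        assert round_half_up(100 * row_ery[2] / row_ery.sum(), 1) == 2.3

    def test_diagonal_matrix_all_hundred(self):
        cm = ConfusionMatrix(("a", "b"), np.array([[5, 0, 0], [0, 7, 0]]), np.zeros(2, int))
        m = metrics_from_confusion(cm)
        for cls in ("a", "b", "macro"):
            assert m[cls].as_percent() == {"precision": 100.0, "recall": 100.0, "f1": 100.0}

    def test_empty_row_reported_missing_with_warning(self):
        cm = ConfusionMatrix(("a", "b"), np.array([[5, 0, 0], [0, 0, 0]]), np.zeros(2, int))
        with pytest.warns(UserWarning, match="'b'"):
            m = metrics_from_confusion(cm)
        assert m["b"].recall is None

    def test_spurious_lowers_precision_not_recall(self):
        base = ConfusionMatrix(("a", "b"), np.array([[8, 1, 1], [2, 6, 2]]), np.zeros(2, int))
        spiked = ConfusionMatrix(("a", "b"), base.counts.copy(), np.array([3, 0]))
        m0, m1 = metrics_from_confusion(base), metrics_from_confusion(spiked)
        assert m1["a"].precision < m0["a"].precision
        assert m1["a"].recall == m0["a"].recall
        assert m1["b"].recall == m0["b"].recall

    def test_row_totals_of_reference_tables(self):
        assert load_reference_table("two_class_optimised").row_totals().tolist() == [98, 242]
        assert load_reference_table("four_class").row_totals().tolist() == [542, 311, 145, 174]
        assert load_reference_table("four_class_redcell_merged").row_totals().tolist() == \
            [853, 145, 174]

    def test_merging_four_class_reproduces_published_merge(self):
        merged = load_reference_table("four_class").merged(
            {0: 0, 1: 0, 2: 1, 3: 2}, ["red cell", "leukocyte", "platelet"])
        published = load_reference_table("four_class_redcell_merged")
        assert np.array_equal(merged.counts, published.counts)


def dataset_of(class_counts, images_per_class, seed=0):
    """Images whose dominant class is fixed, n images per class."""
    images = []
    i = 0
    for cid, n in zip(itertools.count(), images_per_class):
        for _ in range(n):
            anns = [Annotation(cid, NormBox(0.5, 0.5, 0.1, 0.1))] * class_counts
            images.append(LabeledImage(np.zeros((8, 8), np.uint8), list(anns), f"im{i}"))
            i += 1
    return images


class TestStratifiedSplit:
    def test_single_class_fraction_sizes(self):
        ds = dataset_of(1, [100])
        fs = stratified_split(ds, k=5, seed=0)
        for fold in range(5):
            sizes = [len(fs.subset(fold, s)) for s in ("train", "val", "test")]
            assert sizes == [70, 20, 10]

    def test_two_class_ratio_within_one_image(self):
        ds = dataset_of(1, [80, 20])
        fs = stratified_split(ds, k=5, seed=1)
        ids_by_class = {img.source_id: img.annotations[0].class_id for img in ds}
        for fold in range(5):
            for subset, frac in zip(("train", "val", "test"), (0.7, 0.2, 0.1)):
                members = fs.subset(fold, subset)
                for cid, total in ((0, 80), (1, 20)):
                    n = sum(1 for m in members if ids_by_class[m] == cid)
                    assert abs(n - frac * total) <= 1

    def test_same_seed_identical(self):
        ds = dataset_of(1, [30, 30])
        a = stratified_split(ds, seed=7)
        b = stratified_split(ds, seed=7)
        assert a.folds == b.folds

    def test_folds_differ(self):
        ds = dataset_of(1, [50, 50])
        fs = stratified_split(ds, seed=3)
        assert any(fs.folds[0] != fs.folds[i] for i in range(1, 5))

    def test_rare_class_rejected(self):
        ds = dataset_of(1, [40, 3])
        with pytest.raises(ValueError, match="class id 1"):
            stratified_split(ds, k=5)

    def test_partition_property(self):
        ds = dataset_of(1, [23, 41])
        fs = stratified_split(ds, seed=2)
        all_ids = {img.source_id for img in ds}
        for fold in range(fs.k):
            union = set()
            for s in ("train", "val", "test"):
                members = set(fs.subset(fold, s))
                assert not (union & members)
                union |= members
            assert union == all_ids


class TestAggregateFolds:
    def fold(self, p, r=None, f=None):
        p = p / 100
        r = p if r is None else r / 100
        f = (2 * p * r / (p + r)) if f is None else f / 100
        return {"a": ClassMetrics(p, r, f)}

    def test_identical_folds_zero_sd(self):
        rep = aggregate_folds([self.fold(90)] * 5)
        assert rep.sd["a"]["precision"] == 0.0

    def test_hand_computed_mean_and_sample_sd(self):
        rep = aggregate_folds([self.fold(v) for v in (90, 92, 94, 96, 98)])
        assert rep.mean["a"]["precision"] == pytest.approx(94.0)
        assert round_half_up(rep.sd["a"]["precision"], 1) == 3.2

    def test_matches_reference_statistics_routine(self):
        vals = [81.3, 85.2, 79.9, 88.0, 83.3]
        rep = aggregate_folds([self.fold(v) for v in vals])
        assert rep.mean["a"]["precision"] == pytest.approx(np.mean(vals))
        assert rep.sd["a"]["precision"] == pytest.approx(np.std(vals, ddof=1))

    def test_single_fold_rejected(self):
        with pytest.raises(ValueError):
            aggregate_folds([self.fold(90)])

    def test_ragged_class_sets_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            aggregate_folds([self.fold(90), {"b": ClassMetrics(0.9, 0.9, 0.9)}])

    def test_formatted_string(self):
        rep = aggregate_folds([self.fold(v) for v in (90, 92, 94, 96, 98)])
        assert rep.formatted()["a"]["precision"] == "94.0% ± 3.2%"
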
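"""Detection primitives against independent oracles.

IoU is cross-checked with shapely rectangle geometry, NMS with a naive
reference suppression written here, and greedy matching with the exhaustive
maximum bipartite matching (scipy csgraph).
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching
from shapely.geometry import box as shapely_box

from dropletbench import (
    DetBox,
    average_precision,
    confusion_matrix,
    iou,
    match,
    mean_average_precision,
    nms,
)


def shapely_iou(a: DetBox, b: DetBox) -> float:
    ga, gb = (shapely_box(*x.to_corners()) for x in (a, b))
    union = ga.union(gb).area
    return ga.intersection(gb).area / union if union else 0.0


def reference_nms(boxes, thr):
    order = sorted(range(len(boxes)), key=lambda i: (-boxes[i].confidence, i))
    kept = []
    for i in order:
        if all(boxes[i].cls != boxes[j].cls or shapely_iou(boxes[i], boxes[j]) <= thr for j in kept):
            kept.append(i)
    return [boxes[i] for i in kept]


def max_matching_tp(preds, gts, thr):
    """Maximum number of one-to-one pred/gt pairs with same class and IoU >= thr."""
    if not preds or not gts:
        return 0
    adj = np.zeros((len(preds), len(gts)), dtype=int)
    for i, p in enumerate(preds):
        for j, g in enumerate(gts):
            if p.cls == g.cls and iou(p, g) >= thr:
                adj[i, j] = 1
    matching = maximum_bipartite_matching(csr_matrix(adj), perm_type="column")
    return int(np.sum(matching >= 0))


def random_boxes(rng, n, classes=("droplet",), field=40.0):
    return [
        DetBox(
            cx=rng.uniform(0, field),
            cy=rng.uniform(0, field),
            w=rng.uniform(2, 8),
            h=rng.uniform(2, 8),
            cls=classes[rng.integers(len(classes))],
            confidence=float(np.round(rng.uniform(), 6)),
        )
        for _ in range(n)
    ]


class TestIoU:
    def test_identical_and_disjoint(self):
        a = DetBox(5, 5, 4, 4)
        assert iou(a, a) == 1.0
        assert iou(a, DetBox(50, 50, 4, 4)) == 0.0

    def test_half_offset_squares(self):
        # 2x2 squares centered one unit apart: intersection 2, union 6
        assert iou(DetBox(0, 0, 2, 2), DetBox(1, 0, 2, 2)) == pytest.approx(1 / 3)

    @settings(deadline=None, max_examples=100)
    @given(
        vals=st.tuples(*[st.floats(-20, 20) for _ in range(4)]),
        sizes=st.tuples(*[st.floats(0.5, 10) for _ in range(4)]),
    )
    def test_symmetry_and_shapely_agreement(self, vals, sizes):
        a = DetBox(vals[0], vals[1], sizes[0], sizes[1])
        b = DetBox(vals[2], vals[3], sizes[2], sizes[3])
        assert iou(a, b) == pytest.approx(iou(b, a), abs=1e-12)
        assert iou(a, b) == pytest.approx(shapely_iou(a, b), abs=1e-9)


class TestNMS:
    def test_suppresses_lower_confidence_overlap(self):
        hi = DetBox(5, 5, 4, 4, "droplet", 0.9)
        lo = DetBox(5.5, 5, 4, 4, "droplet", 0.7)
        assert nms([lo, hi], 0.45) == [hi]

    def test_classwise_rule_keeps_other_class(self):
        hi = DetBox(5, 5, 4, 4, "droplet", 0.9)
        other = DetBox(5.5, 5, 4, 4, "cell", 0.7)
        assert set(nms([hi, other], 0.45)) == {hi, other}

    def test_matches_reference_on_random_instances(self, rng):
        for _ in range(25):
            boxes = random_boxes(rng, 50, classes=("droplet", "cell"))
            for thr in (0.3, 0.45, 0.6):
                assert nms(boxes, thr) == reference_nms(boxes, thr)

    def test_output_pairwise_separated(self, rng):
        boxes = random_boxes(rng, 80)
        kept = nms(boxes, 0.45)
        assert all(
            iou(kept[i], kept[j]) <= 0.45
            for i in range(len(kept))
            for j in range(i + 1, len(kept))
            if kept[i].cls == kept[j].cls
        )


class TestMatch:
    def test_single_true_positive(self):
        m = match([DetBox(5, 5, 4, 4, "droplet", 0.9)], [DetBox(5, 5, 4, 4)])
        assert (m.tp, m.fp, m.fn) == ({"droplet": 1}, {"droplet": 0}, {"droplet": 0})

    def test_duplicate_prediction_is_fp(self):
        preds = [DetBox(5, 5, 4, 4, "droplet", 0.9), DetBox(5.2, 5, 4, 4, "droplet", 0.8)]
        m = match(preds, [DetBox(5, 5, 4, 4)])
        assert m.tp["droplet"] == 1 and m.fp["droplet"] == 1 and m.fn["droplet"] == 0

    def test_conservation_and_near_optimality(self, rng):
        """Greedy tp is within one of the exhaustive maximum matching; totals conserve."""
        gaps = []
        for _ in range(60):
            preds = random_boxes(rng, 10)
            gts = random_boxes(rng, 10)
            m = match(preds, gts, 0.3)
            assert m.tp["droplet"] + m.fn["droplet"] == len(gts)
            assert m.tp["droplet"] + m.fp["droplet"] == len(preds)
            opt = max_matching_tp(preds, gts, 0.3)
            assert m.tp["droplet"] <= opt
            gaps.append(opt - m.tp["droplet"])
        assert max(gaps) <= 1  # documented greedy difference
        assert gaps.count(0) >= len(gaps) * 0.9


class TestAveragePrecision:
    def test_perfect_detector(self):
        gts = [DetBox(5, 5, 4, 4), DetBox(20, 20, 4, 4)]
        preds = [DetBox(5, 5, 4, 4, "droplet", 0.9), DetBox(20, 20, 4, 4, "droplet", 0.8)]
        for thr in (0.5, 0.75, 0.95):
            assert average_precision([(preds, gts)], "droplet", thr).ap == 1.0

    def test_no_detections(self):
        assert average_precision([([], [DetBox(5, 5, 4, 4)])], "droplet").ap == 0.0

    def test_absent_class_flagged(self):
        with pytest.raises(ValueError, match="absent"):
            average_precision([([], [DetBox(5, 5, 4, 4, "droplet")])], "cell")

    def test_trailing_fp_does_not_reduce_all_point_ap(self):
        """1 GT matched at conf 0.9 plus an unmatched 0.8 box: envelope AP stays 1."""
        preds = [DetBox(5, 5, 4, 4, "droplet", 0.9), DetBox(30, 30, 4, 4, "droplet", 0.8)]
        curve = average_precision([(preds, [DetBox(5, 5, 4, 4)])], "droplet")
        assert curve.ap == 1.0
        assert list(curve.recall) == [1.0, 1.0]

    def test_recall_monotone_in_threshold(self, rng):
        preds = random_boxes(rng, 30)
        gts = random_boxes(rng, 15)
        curve = average_precision([(preds, gts)], "droplet", 0.3)
        assert np.all(np.diff(curve.recall) >= 0)

    def test_ap_decreases_with_stricter_iou(self, rng):
        for _ in range(10):
            preds = random_boxes(rng, 20)
            gts = random_boxes(rng, 10)
            images = [(preds, gts)]
            assert (
                average_precision(images, "droplet", 0.5).ap
                >= average_precision(images, "droplet", 0.75).ap
            )

    def test_map_of_perfect_detector(self):
        gts = [DetBox(5, 5, 4, 4, "droplet"), DetBox(20, 20, 3, 3, "cell")]
        assert mean_average_precision([(gts, gts)]) == 1.0


class TestConfusionMatrix:
    def test_all_correct(self):
        gts = [DetBox(10 * i + 5, 5, 4, 4, "droplet") for i in range(5)]
        table, metrics = confusion_matrix(gts, gts)
        assert table.loc["droplet", "droplet"] == 5
        assert metrics["droplet"] == {"precision": 100.0, "recall": 100.0}

    def test_empty_predictions(self):
        gts = [DetBox(10 * i + 5, 5, 4, 4, "droplet") for i in range(3)]
        table, metrics = confusion_matrix([], gts)
        assert table.loc["background", "droplet"] == 3
        assert metrics["droplet"]["recall"] == 0.0

    def test_printed_precision_formula(self):
        """4999 TP + 1 FP + 1 FN prints as 99.980% precision and recall."""
        preds, gts = [], []
        for i in range(4999):
            b = DetBox((i % 100) * 10 + 5, (i // 100) * 10 + 5, 4, 4, "success", 0.9)
            preds.append(b)
            gts.append(DetBox(b.cx, b.cy, 4, 4, "success"))
        preds.append(DetBox(2005, 5, 4, 4, "success", 0.9))  # false positive
        gts.append(DetBox(2005, 505, 4, 4, "success"))  # missed ground truth
        _, metrics = confusion_matrix(preds, gts)
        assert f"{metrics['success']['precision']:.3f}" == "99.980"
        assert f"{metrics['success']['recall']:.3f}" == "99.980"
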
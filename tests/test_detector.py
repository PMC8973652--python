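"""Detector: box geometry, encode/decode, NMS, anchors, keypoint assignment."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perioscan.nn import parameter_count
from perioscan.pbl_core import KeypointSet, Point2D
from perioscan.detector import (
    AnchorSet,
    CropGeometry,
    Detection,
    DetectorConfig,
    EmptyDataset,
    IncompleteDetection,
    TooFewBoxes,
    assign_keypoints,
    box_center,
    build_detector,
    ciou,
    compute_anchors,
    decode_head,
    encode_box,
    iou,
    keypoints_to_boxes,
    nms,
    train_detector,
)

boxes_st = st.tuples(
    st.floats(0, 80), st.floats(0, 80), st.floats(1, 40), st.floats(1, 40)
).map(lambda t: (t[0], t[1], t[0] + t[2], t[1] + t[3]))


class TestIoU:
    def test_identical(self):
        assert iou((0, 0, 10, 10), (0, 0, 10, 10)) == 1.0

    def test_disjoint(self):
        assert iou((0, 0, 10, 10), (20, 20, 30, 30)) == 0.0

    def test_hand_computed_overlap(self):
        assert iou((0, 0, 10, 10), (5, 0, 15, 10)) == pytest.approx(1 / 3)


class TestCIoU:
    def test_identical_boxes(self):
        assert ciou((2, 3, 12, 9), (2, 3, 12, 9)) == pytest.approx(1.0)

    def test_offset_centres_penalized(self):
        a, b = (0, 0, 10, 10), (4, 0, 14, 10)
        assert ciou(a, b) < iou(a, b)

    def test_fixed_pair_matches_independent_formula(self):
        a, b = (0.0, 0.0, 10.0, 20.0), (5.0, 2.0, 25.0, 12.0)
        i = iou(a, b)
        d2 = ((5.0 - 15.0) ** 2 + (10.0 - 7.0) ** 2)
        c2 = (25.0 - 0.0) ** 2 + (20.0 - 0.0) ** 2
        v = 4 / math.pi**2 * (math.atan(10 / 20) - math.atan(20 / 10)) ** 2
        alpha = v / (1 - i + v)
        assert ciou(a, b) == pytest.approx(i - d2 / c2 - alpha * v, abs=1e-9)

    @settings(max_examples=200, derandomize=True)
    @given(a=boxes_st, b=boxes_st)
    def test_never_exceeds_iou(self, a, b):
        assert ciou(a, b) <= iou(a, b) + 1e-12

    def test_equality_requires_matching_centres_and_aspect(self):
        # same centre, same aspect ratio, different size: penalties vanish
        a, b = (0, 0, 20, 10), (5, 2.5, 15, 7.5)
        assert ciou(a, b) == pytest.approx(iou(a, b), abs=1e-12)


class TestNMS:
    def test_highest_score_survives(self):
        d = [
            Detection((0, 0, 10, 10), "cej", 0.9),
            Detection((0, 0, 10, 10), "cej", 0.8),
        ]
        out = nms(d, 0.5)
        assert len(out) == 1 and out[0].score == 0.9

    def test_disjoint_all_survive(self):
        d = [
            Detection((0, 0, 10, 10), "cej", 0.9),
            Detection((50, 50, 60, 60), "cej", 0.1),
        ]
        assert len(nms(d, 0.5)) == 2

    def test_classes_do_not_suppress_each_other(self):
        d = [
            Detection((0, 0, 10, 10), "cej", 0.9),
            Detection((0, 0, 10, 10), "crest", 0.8),
        ]
        assert len(nms(d, 0.5)) == 2

    def test_idempotent_on_random_instances(self, rng):
        for _ in range(30):
            dets = [
                Detection(
                    (x0 := rng.uniform(0, 50), y0 := rng.uniform(0, 50),
                     x0 + rng.uniform(2, 30), y0 + rng.uniform(2, 30)),
                    rng.choice(["cej", "crest"]),
                    float(rng.random()),
                )
                for _ in range(12)
            ]
            once = nms(dets, 0.4)
            twice = nms(once, 0.4)
            assert [(d.box, d.score) for d in twice] == [(d.box, d.score) for d in once]
            assert len(once) <= len(dets)
            assert {d.score for d in once} <= {d.score for d in dets}


class TestKeypointBoxes:
    def test_box_arithmetic(self):
        kp = KeypointSet(
            m1=Point2D(40, 50), m2=Point2D(40, 60), m3=Point2D(40, 90),
            d1=Point2D(60, 50), d2=Point2D(60, 70), d3=Point2D(60, 90),
        )
        boxes = dict()
        for cls, box in keypoints_to_boxes(kp, side=12):
            boxes.setdefault(cls, []).append(box)
        assert boxes["cej"][0] == (34, 44, 46, 56)

    def test_round_trip_recovers_points(self):
        kp = KeypointSet(
            m1=Point2D(40.5, 50.25), m2=Point2D(41, 60), m3=Point2D(42, 90),
            d1=Point2D(60, 50), d2=Point2D(61, 70), d3=Point2D(62, 90),
        )
        pts = list(kp.points().values())
        for (cls, box), p in zip(keypoints_to_boxes(kp, 10), pts):
            c = box_center(box)
            assert (c.x, c.y) == (p.x, p.y)

    def test_unirooted_apex_boxes_coincide(self):
        apex = Point2D(50, 90)
        kp = KeypointSet(
            m1=Point2D(40, 50), m2=Point2D(42, 60), m3=apex,
            d1=Point2D(60, 50), d2=Point2D(58, 70), d3=apex, unirooted=True,
        )
        boxes = [b for c, b in keypoints_to_boxes(kp) if c == "apex"]
        assert boxes[0] == boxes[1]


class TestEncodeDecode:
    def test_round_trip_within_half_pixel(self, rng):
        cfg = DetectorConfig()
        for _ in range(50):
            si = int(rng.integers(0, 2))
            stride = cfg.strides[si]
            ai = int(rng.integers(0, 2))
            anchor = cfg.anchors.per_scale[si][ai]
            w, h = rng.uniform(6, 30, size=2)
            cx = rng.uniform(w / 2 + 1, cfg.input_hw[1] - w / 2 - 1)
            cy = rng.uniform(h / 2 + 1, cfg.input_hw[0] - h / 2 - 1)
            box = (cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)
            gx, gy, tx, ty, tw, th = encode_box(box, stride, anchor)
            gh, gw = cfg.input_hw[0] // stride, cfg.input_hw[1] // stride
            head = np.zeros((1, cfg.n_anchors * 10, gh, gw), np.float32)
            vec = head.reshape(1, cfg.n_anchors, 10, gh, gw)
            vec[0, ai, 0:4, gy, gx] = (tx, ty, tw, th)
            dec = decode_head(head, stride, cfg.anchors.per_scale[si], 5)
            got = dec["boxes"][0, ai, gy, gx]
            assert np.abs(np.asarray(got) - np.asarray(box)).max() < 0.5


class TestComputeAnchors:
    def test_identical_boxes_collapse(self):
        boxes = [(0, 0, 12, 12)] * 10
        anchors = compute_anchors(boxes, k_per_scale=2, n_scales=2, seed=0)
        for scale in anchors.per_scale:
            for w, h in scale:
                assert (w, h) == (12.0, 12.0)

    def test_two_clusters_recovered(self):
        small = [(0, 0, 10 + d, 10 + d) for d in (0, 1, 2, 3)]
        large = [(0, 0, 40 + d, 40 + d) for d in (0, 1, 2, 3)]
        anchors = compute_anchors(small + large, k_per_scale=1, n_scales=2, seed=1)
        (w1, h1), = anchors.per_scale[0]
        (w2, h2), = anchors.per_scale[1]
        assert w1 == pytest.approx(11.5) and w2 == pytest.approx(41.5)

    def test_deterministic(self, rng):
        boxes = [
            (0, 0, float(rng.uniform(5, 50)), float(rng.uniform(5, 50)))
            for _ in range(30)
        ]
        a = compute_anchors(boxes, seed=3)
        b = compute_anchors(boxes, seed=3)
        assert a.per_scale == b.per_scale

    def test_too_few_boxes(self):
        with pytest.raises(TooFewBoxes):
            compute_anchors([(0, 0, 5, 5)], k_per_scale=2, n_scales=2)


class TestNetwork:
    def test_forward_shape_contract(self, rng):
        cfg = DetectorConfig()
        model = build_detector(cfg)
        x = rng.random((1, 1, 96, 160)).astype(np.float32)
        h3, h4 = model.forward(x, train=False)
        per_anchor = 5 + len(cfg.class_names)
        assert h3.shape == (1, cfg.n_anchors * per_anchor, 12, 20)
        assert h4.shape == (1, cfg.n_anchors * per_anchor, 6, 10)

    def test_width_multiplier_grows_capacity(self):
        n_small = parameter_count(build_detector(DetectorConfig(width_mult=0.5)).params)
        n_big = parameter_count(build_detector(DetectorConfig(width_mult=1.0)).params)
        assert n_small < n_big

    def test_same_seed_identical_parameters(self):
        a, b = build_detector(DetectorConfig(seed=4)), build_detector(DetectorConfig(seed=4))
        for pa, pb in zip(a.params, b.params):
            assert np.array_equal(pa.value, pb.value)

    def test_empty_dataset_rejected(self):
        model = build_detector(DetectorConfig())
        with pytest.raises(EmptyDataset):
            train_detector(model, [], model.config)

    def test_zero_learning_rate_freezes_loss(self, rng):
        cfg = DetectorConfig(epochs=3, learning_rate=0.0, batch_size=2)
        model = build_detector(cfg)
        crop = rng.integers(0, 255, size=(100, 70)).astype(np.uint8)
        samples = [(crop, [(0, (30.0, 40.0, 42.0, 52.0))])] * 2
        _, history = train_detector(model, samples, cfg)
        assert max(history) - min(history) < 1e-5


class TestAssignKeypoints:
    GEOM = CropGeometry(width=100, height=140, mesial_side="right")

    @staticmethod
    def det(cls, x, y, score=0.9):
        return Detection((x - 5, y - 5, x + 5, y + 5), cls, score)

    def test_full_set_from_six_detections(self):
        dets = [
            self.det("cej", 30, 60), self.det("cej", 70, 60),
            self.det("crest", 32, 70), self.det("crest", 68, 72),
            self.det("apex", 40, 120), self.det("apex", 60, 120),
        ]
        kp, v, f = assign_keypoints(dets, self.GEOM)
        # mesial side declared right: m-points are the larger-x ones
        assert kp.m1 == Point2D(70, 60) and kp.d1 == Point2D(30, 60)
        assert kp.m2 == Point2D(68, 72) and kp.d2 == Point2D(32, 70)
        assert kp.m3 == Point2D(60, 120) and kp.d3 == Point2D(40, 120)
        assert not v and not f and not kp.unirooted

    def test_single_apex_duplicates_to_both_sides(self):
        dets = [
            self.det("cej", 30, 60), self.det("cej", 70, 60),
            self.det("crest", 32, 70), self.det("crest", 68, 72),
            self.det("apex", 50, 120),
        ]
        kp, _, _ = assign_keypoints(dets, self.GEOM)
        assert kp.unirooted and kp.m3 == kp.d3 == Point2D(50, 120)

    def test_missing_role_raises(self):
        dets = [
            self.det("cej", 30, 60), self.det("cej", 70, 60),
            self.det("apex", 50, 120),
        ]
        with pytest.raises(IncompleteDetection) as exc:
            assign_keypoints(dets, self.GEOM)
        assert exc.value.missing_roles == ["crest"]

    def test_one_sided_miss_mirrors_complete_side(self):
        """A lone crest pairs with its own side's CEJ, never the opposite one."""
        dets = [
            self.det("cej", 30, 60), self.det("cej", 70, 60),
            self.det("crest", 68, 90),  # right side only, deep crest
            self.det("apex", 40, 120), self.det("apex", 60, 120),
        ]
        kp, _, _ = assign_keypoints(dets, self.GEOM)
        # right (mesial) side is complete; left inherits the whole right triple
        assert kp.m1 == kp.d1 == Point2D(70, 60)
        assert kp.m2 == kp.d2 == Point2D(68, 90)

    def test_lesion_flags_from_surviving_detections(self):
        dets = [
            self.det("cej", 30, 60), self.det("cej", 70, 60),
            self.det("crest", 32, 70), self.det("crest", 68, 72),
            self.det("apex", 50, 120),
            self.det("furcation_lesion", 50, 100, 0.7),
        ]
        _, v, f = assign_keypoints(dets, self.GEOM)
        assert f and not v
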
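"""Stage 2: single-stage detector for keypoints and lesion boxes on crops.

A scaled-down YOLO-family detector runs on each tooth crop.  The backbone
stacks cross-stage-partial (CSP) blocks, the neck combines a spatial-pyramid
-pooling block (stride-1 max pools of several sizes, concatenated) with
top-down + bottom-up feature fusion (PAN), and per-scale 1x1 heads emit, for
every anchor and grid cell, box offsets, an objectness logit and class
logits.  Boxes are regressed with the complete-IoU (CIoU) loss; objectness
and classes with binary cross-entropy.

Keypoints are detected as objects: each landmark becomes a small square box
(12 px by default) centred on the point, with three appearance classes (cej,
crest, apex); whether a point is mesial or distal is a spatial attribute and
is resolved afterwards from the detection's position and the crop's declared
mesial side.  The two lesion categories (vertical defect, furcation
radiolucency) are ordinary object classes.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from skimage.transform import resize as _sk_resize

from . import nn
from .metrics import box_iou
from .pbl_core import KeypointSet, Point2D, ToothAnnotation

Box = tuple[float, float, float, float]  # half-open (x0, y0, x1, y1)

CLASS_NAMES = ("cej", "crest", "apex", "vertical_lesion", "furcation_lesion")
KEYPOINT_CLASSES = ("cej", "crest", "apex")


class EmptyDataset(ValueError):
    pass


class NonFiniteLoss(RuntimeError):
    pass


class TooFewBoxes(ValueError):
    pass


class IncompleteDetection(RuntimeError):
    """A tooth whose detections miss at least one keypoint role entirely."""

    def __init__(self, missing_roles: Sequence[str]) -> None:
        self.missing_roles = list(missing_roles)
        super().__init__(f"missing keypoint roles: {', '.join(self.missing_roles)}")


@dataclass
class Detection:
    """One predicted box in crop coordinates; score = objectness x class prob."""

    box: Box
    class_name: str
    score: float


@dataclass
class AnchorSet:
    """Per-scale (w, h) anchor priors, each scale sorted by area."""

    per_scale: list[list[tuple[float, float]]]

    def __post_init__(self) -> None:
        for anchors in self.per_scale:
            if any(w <= 0 or h <= 0 for w, h in anchors):
                raise ValueError("anchor dimensions must be positive")
            anchors.sort(key=lambda wh: wh[0] * wh[1])


@dataclass
class DetectorConfig:
    """Architecture, anchor and training defaults for the crop detector.

    ``input_hw`` is the (height, width) every crop is resized to before the
    forward pass (both divisible by 16); detections are mapped back to crop
    coordinates.  ``width_mult``/``depth_mult`` scale channel counts and CSP
    repeats; the defaults give a desk-scale model of a few thousand weights.
    """

    input_hw: tuple[int, int] = (128, 80)
    width_mult: float = 1.0
    depth_mult: float = 1.0
    n_anchors: int = 2
    class_names: tuple[str, ...] = CLASS_NAMES
    anchors: AnchorSet = field(
        default_factory=lambda: AnchorSet(
            [[(10.0, 10.0), (14.0, 14.0)], [(18.0, 12.0), (26.0, 20.0)]]
        )
    )
    confidence_threshold: float = 0.2
    nms_iou: float = 0.45
    keypoint_box_side: float = 12.0
    epochs: int = 90
    learning_rate: float = 3e-3
    batch_size: int = 8
    seed: int = 0
    strides: tuple[int, int] = (8, 16)
    obj_pos_weight: float = 4.0
    box_weight: float = 2.0

    def validate(self) -> None:
        if self.keypoint_box_side < 4:
            raise ValueError("keypoint box side must be >= 4 px")
        if any(d % 16 for d in self.input_hw):
            raise ValueError("input size must be divisible by 16")
        if len(self.anchors.per_scale) != len(self.strides):
            raise ValueError("one anchor list per scale required")


# ---------------------------------------------------------------------------
# Box geometry: IoU, CIoU, NMS
# ---------------------------------------------------------------------------

def iou(box_a: Box, box_b: Box) -> float:
    """Intersection-over-union of two half-open boxes."""
    return box_iou(box_a, box_b)


def ciou(box_a: Box, box_b: Box) -> float:
    """Complete IoU: IoU minus centre-distance and aspect-ratio penalties.

    ``IoU - d^2/c^2 - alpha*v`` with d the centre distance, c the diagonal of
    the smallest enclosing box, ``v = (4/pi^2) (atan wA/hA - atan wB/hB)^2``
    and ``alpha = v / (1 - IoU + v)``.  Equals IoU when the centres coincide
    and the aspect ratios match; never exceeds IoU.
    """
    i = box_iou(box_a, box_b)
    ax, ay = (box_a[0] + box_a[2]) / 2, (box_a[1] + box_a[3]) / 2
    bx, by = (box_b[0] + box_b[2]) / 2, (box_b[1] + box_b[3]) / 2
    cw = max(box_a[2], box_b[2]) - min(box_a[0], box_b[0])
    ch = max(box_a[3], box_b[3]) - min(box_a[1], box_b[1])
    c2 = cw * cw + ch * ch
    d2 = (ax - bx) ** 2 + (ay - by) ** 2
    wa, ha = box_a[2] - box_a[0], box_a[3] - box_a[1]
    wb, hb = box_b[2] - box_b[0], box_b[3] - box_b[1]
    v = (4.0 / math.pi**2) * (math.atan(wa / max(ha, 1e-9)) - math.atan(wb / max(hb, 1e-9))) ** 2
    alpha = v / (1.0 - i + v + 1e-12)
    return i - (d2 / c2 if c2 > 0 else 0.0) - alpha * v


def nms(detections: Sequence[Detection], iou_threshold: float = 0.45) -> list[Detection]:
    """Greedy per-class suppression: keep the best, drop overlaps above IoU.

    Idempotent; the output is a subset of the input, in score-descending
    order within each class.
    """
    kept: list[Detection] = []
    for cls in {d.class_name for d in detections}:
        group = sorted(
            (d for d in detections if d.class_name == cls),
            key=lambda d: (-d.score, d.box),
        )
        chosen: list[Detection] = []
        for d in group:
            if all(box_iou(d.box, k.box) <= iou_threshold for k in chosen):
                chosen.append(d)
        kept.extend(chosen)
    return kept


# ---------------------------------------------------------------------------
# Keypoint <-> box encoding
# ---------------------------------------------------------------------------

def keypoints_to_boxes(kp: KeypointSet, side: float = 12.0) -> list[tuple[str, Box]]:
    """One square box per landmark, classed by role; centre recovers the point.

    Returns six (class, box) pairs in the order m1, m2, m3, d1, d2, d3; the
    apex boxes of a unirooted tooth coincide.
    """
    role = {"1": "cej", "2": "crest", "3": "apex"}
    out: list[tuple[str, Box]] = []
    for name, p in kp.points().items():
        h = side / 2.0
        out.append((role[name[1]], (p.x - h, p.y - h, p.x + h, p.y + h)))
    return out


def box_center(box: Box) -> Point2D:
    return Point2D((box[0] + box[2]) / 2.0, (box[1] + box[3]) / 2.0)


def targets_from_annotation(
    ann: ToothAnnotation, offset: Point2D, crop_hw: tuple[int, int],
    keypoint_box_side: float = 12.0,
) -> list[tuple[int, Box]]:
    """Detection targets, in crop coordinates, for one annotated tooth.

    Keypoint boxes come from :func:`keypoints_to_boxes` (coincident unirooted
    apex boxes deduplicated); lesion boxes are carried over with their class.
    Boxes falling outside the crop are clipped; degenerate ones dropped.
    """
    h, w = crop_hw
    targets: list[tuple[int, Box]] = []
    seen: set[tuple] = set()
    shifted = KeypointSet(
        **{
            name: Point2D(p.x - offset.x, p.y - offset.y)
            for name, p in ann.keypoints.points().items()
        },
        tooth_id=ann.tooth_id,
        unirooted=ann.unirooted,
    )
    for cls, box in keypoints_to_boxes(shifted, keypoint_box_side):
        key = (cls, tuple(round(v, 3) for v in box))
        if key in seen:
            continue
        seen.add(key)
        targets.append((CLASS_NAMES.index(cls), box))
    for lb in ann.lesion_boxes:
        x0, y0, x1, y1 = lb["box"]
        box = (x0 - offset.x, y0 - offset.y, x1 - offset.x, y1 - offset.y)
        cls = "vertical_lesion" if lb["class"] == "vertical" else "furcation_lesion"
        targets.append((CLASS_NAMES.index(cls), box))
    clipped: list[tuple[int, Box]] = []
    for ci, (x0, y0, x1, y1) in targets:
        x0, y0 = max(0.0, x0), max(0.0, y0)
        x1, y1 = min(float(w), x1), min(float(h), y1)
        if x1 - x0 >= 2.0 and y1 - y0 >= 2.0:
            clipped.append((ci, (x0, y0, x1, y1)))
    return clipped


# ---------------------------------------------------------------------------
# Anchor estimation
# ---------------------------------------------------------------------------

def _wh_iou(wh_a: tuple[float, float], wh_b: tuple[float, float]) -> float:
    inter = min(wh_a[0], wh_b[0]) * min(wh_a[1], wh_b[1])
    union = wh_a[0] * wh_a[1] + wh_b[0] * wh_b[1] - inter
    return inter / union if union > 0 else 0.0


def compute_anchors(
    boxes: Sequence[Box], k_per_scale: int = 2, n_scales: int = 2, seed: int = 0,
    max_iter: int = 100,
) -> AnchorSet:
    """K-means on box (w, h) under IoU distance (1 - IoU of centred boxes).

    Runs one k-means with ``k = k_per_scale * n_scales`` clusters and splits
    the area-sorted centroids across scales (small anchors to the fine
    scale).  Centres start at area quantiles of the distinct shapes, so the
    result is deterministic (``seed`` only perturbs exact ties, if ever).
    """
    k = k_per_scale * n_scales
    whs = [(b[2] - b[0], b[3] - b[1]) for b in boxes]
    if len(whs) < k:
        raise TooFewBoxes(f"need at least {k} boxes, got {len(whs)}")
    uniq = sorted(set(whs), key=lambda wh: (wh[0] * wh[1], wh))
    if len(uniq) <= k:
        centers = list(uniq) + [uniq[-1]] * (k - len(uniq))
    else:
        centers = [
            uniq[round(i * (len(uniq) - 1) / (k - 1))] if k > 1 else uniq[len(uniq) // 2]
            for i in range(k)
        ]
    assign = None
    for _ in range(max_iter):
        new_assign = [
            max(range(k), key=lambda ci: _wh_iou(wh, centers[ci])) for wh in whs
        ]
        if new_assign == assign:
            break
        assign = new_assign
        for ci in range(k):
            members = [wh for wh, a in zip(whs, assign) if a == ci]
            if members:
                centers[ci] = (
                    float(np.mean([m[0] for m in members])),
                    float(np.mean([m[1] for m in members])),
                )
    centers.sort(key=lambda wh: wh[0] * wh[1])
    return AnchorSet(
        [centers[s * k_per_scale : (s + 1) * k_per_scale] for s in range(n_scales)]
    )


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

class _CSPBlock:
    """Stride-2 downsample followed by a cross-stage-partial split/merge."""

    def __init__(self, rng: np.random.Generator, in_ch: int, out_ch: int, repeats: int) -> None:
        half = out_ch // 2
        self.down = nn.conv_block(rng, in_ch, out_ch, stride=2)
        self.part_a = nn.conv_block(rng, out_ch, half, k=1)
        self.part_b = nn.conv_block(rng, out_ch, half, k=1)
        self.bottleneck = nn.Sequential(
            *[layer for _ in range(repeats) for layer in nn.conv_block(rng, half, half).layers]
        )
        self.fuse = nn.conv_block(rng, 2 * half, out_ch, k=1)
        self.half = half

    @property
    def params(self) -> list[nn.Param]:
        return [
            p
            for blk in (self.down, self.part_a, self.part_b, self.bottleneck, self.fuse)
            for p in blk.params
        ]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        d = self.down.forward(x, train=train)
        a = self.part_a.forward(d, train=train)
        b = self.bottleneck.forward(self.part_b.forward(d, train=train), train=train)
        return self.fuse.forward(np.concatenate([a, b], axis=1), train=train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.fuse.backward(grad)
        ga, gb = g[:, : self.half], g[:, self.half :]
        gd = self.part_a.backward(ga)
        gd = gd + self.part_b.backward(self.bottleneck.backward(gb))
        return self.down.backward(gd)


class _SPP:
    """Spatial pyramid pooling: identity + 3x3 + 5x5 stride-1 max pools, fused."""

    def __init__(self, rng: np.random.Generator, ch: int) -> None:
        self.pool3 = nn.MaxPoolSame(3)
        self.pool5 = nn.MaxPoolSame(5)
        self.fuse = nn.conv_block(rng, 3 * ch, ch, k=1)
        self.ch = ch

    @property
    def params(self) -> list[nn.Param]:
        return self.fuse.params

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        cat = np.concatenate(
            [x, self.pool3.forward(x, train=train), self.pool5.forward(x, train=train)],
            axis=1,
        )
        return self.fuse.forward(cat, train=train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.fuse.backward(grad)
        c = self.ch
        return g[:, :c] + self.pool3.backward(g[:, c : 2 * c]) + self.pool5.backward(g[:, 2 * c :])


class YoloDetector:
    """CSP backbone + SPP/PAN neck + two per-scale heads."""

    BASE_CHANNELS = (8, 16, 24, 32)

    def __init__(self, config: DetectorConfig) -> None:
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        wm = config.width_mult
        c0, c1, c2, c3 = (max(4, int(round(c * wm))) for c in self.BASE_CHANNELS)
        reps = max(1, round(config.depth_mult))
        nc = len(config.class_names)
        self.out_per_anchor = 5 + nc
        head_ch = config.n_anchors * self.out_per_anchor

        self.stem = nn.conv_block(rng, 1, c0, stride=2)  # /2
        self.stage1 = _CSPBlock(rng, c0, c1, reps)  # /4
        self.stage2 = _CSPBlock(rng, c1, c2, reps)  # /8  -> P3
        self.stage3 = _CSPBlock(rng, c2, c3, reps)  # /16 -> P4
        self.spp = _SPP(rng, c3)
        lat = c1
        self.lateral = nn.conv_block(rng, c3, lat, k=1)
        self.up = nn.Upsample2()
        self.n3_conv = nn.conv_block(rng, c2 + lat, c2)
        self.down_conv = nn.conv_block(rng, c2, lat, stride=2)
        self.n4_conv = nn.conv_block(rng, 2 * lat, c3)
        self.head3 = nn.Conv2d(rng, c2, head_ch, k=1)
        self.head4 = nn.Conv2d(rng, c3, head_ch, k=1)
        self._lat_ch, self._p3_ch = lat, c2

    @property
    def params(self) -> list[nn.Param]:
        blocks = (
            self.stem, self.stage1, self.stage2, self.stage3, self.spp,
            self.lateral, self.n3_conv, self.down_conv, self.n4_conv,
        )
        ps = [p for b in blocks for p in b.params]
        ps.extend(self.head3.params)
        ps.extend(self.head4.params)
        return ps

    def forward(self, x: np.ndarray, train: bool = True) -> tuple[np.ndarray, np.ndarray]:
        """Raw head outputs at strides 8 and 16: (N, A*(5+C), H/s, W/s)."""
        h = self.stem.forward(x, train=train)
        h = self.stage1.forward(h, train=train)
        p3 = self.stage2.forward(h, train=train)
        p4 = self.spp.forward(self.stage3.forward(p3, train=train), train=train)
        lat = self.lateral.forward(p4, train=train)
        n3 = self.n3_conv.forward(
            np.concatenate([p3, self.up.forward(lat, train=train)], axis=1), train=train
        )
        dn = self.down_conv.forward(n3, train=train)
        n4 = self.n4_conv.forward(np.concatenate([lat, dn], axis=1), train=train)
        return self.head3.forward(n3, train=train), self.head4.forward(n4, train=train)

    def backward(self, g3: np.ndarray, g4: np.ndarray) -> None:
        g_n4 = self.head4.backward(g4)
        g_cat4 = self.n4_conv.backward(g_n4)
        g_lat = g_cat4[:, : self._lat_ch]
        g_n3 = self.head3.backward(g3) + self.down_conv.backward(g_cat4[:, self._lat_ch :])
        g_cat3 = self.n3_conv.backward(g_n3)
        g_p3_skip = g_cat3[:, : self._p3_ch]
        g_lat = g_lat + self.up.backward(g_cat3[:, self._p3_ch :])
        g_p4 = self.lateral.backward(g_lat)
        g_p3 = self.stage3.backward(self.spp.backward(g_p4)) + g_p3_skip
        g = self.stage2.backward(g_p3)
        g = self.stage1.backward(g)
        self.stem.backward(g)


def build_detector(config: DetectorConfig | None = None) -> YoloDetector:
    return YoloDetector(config or DetectorConfig())


# ---------------------------------------------------------------------------
# Encode / decode
# ---------------------------------------------------------------------------

def _grid(gh: int, gw: int) -> tuple[np.ndarray, np.ndarray]:
    gy, gx = np.mgrid[0:gh, 0:gw]
    return gx.astype(np.float32), gy.astype(np.float32)


def decode_head(
    head_out: np.ndarray, stride: int, anchors: Sequence[tuple[float, float]],
    n_classes: int,
) -> dict[str, np.ndarray]:
    """Raw head tensor -> decoded boxes, objectness and class probabilities.

    Returns arrays shaped (N, A, gh, gw, ...): ``boxes`` (..., 4) half-open,
    ``obj`` and ``cls`` (..., C) as probabilities.
    """
    n, ch, gh, gw = head_out.shape
    a = len(anchors)
    out = head_out.reshape(n, a, 5 + n_classes, gh, gw).transpose(0, 1, 3, 4, 2)
    gx, gy = _grid(gh, gw)
    bx = (nn.sigmoid(out[..., 0]) + gx) * stride
    by = (nn.sigmoid(out[..., 1]) + gy) * stride
    aw = np.array([wh[0] for wh in anchors], dtype=np.float32)[:, None, None]
    ah = np.array([wh[1] for wh in anchors], dtype=np.float32)[:, None, None]
    bw = aw * np.exp(np.clip(out[..., 2], -8, 8))
    bh = ah * np.exp(np.clip(out[..., 3], -8, 8))
    boxes = np.stack([bx - bw / 2, by - bh / 2, bx + bw / 2, by + bh / 2], axis=-1)
    return {
        "boxes": boxes,
        "obj": nn.sigmoid(out[..., 4]),
        "cls": nn.sigmoid(out[..., 5:]),
    }


def encode_box(
    box: Box, stride: int, anchor: tuple[float, float]
) -> tuple[int, int, float, float, float, float]:
    """Inverse of the decode map: (cell_x, cell_y, tx, ty, tw, th)."""
    bx, by = (box[0] + box[2]) / 2, (box[1] + box[3]) / 2
    bw, bh = box[2] - box[0], box[3] - box[1]
    cx, cy = int(bx / stride), int(by / stride)
    fx = np.clip(bx / stride - cx, 1e-4, 1 - 1e-4)
    fy = np.clip(by / stride - cy, 1e-4, 1 - 1e-4)
    tx = float(np.log(fx / (1 - fx)))
    ty = float(np.log(fy / (1 - fy)))
    tw = float(np.log(max(bw, 1e-6) / anchor[0]))
    th = float(np.log(max(bh, 1e-6) / anchor[1]))
    return cx, cy, tx, ty, tw, th


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _resize_crop(crop: np.ndarray, input_hw: tuple[int, int]) -> tuple[np.ndarray, float, float]:
    """Resize to the network input; returns (image, sx, sy) scale factors."""
    h, w = crop.shape
    ih, iw = input_hw
    img = _sk_resize(
        crop.astype(np.float32) / 255.0, (ih, iw), order=1,
        preserve_range=True, anti_aliasing=False,
    ).astype(np.float32)
    return img, iw / w, ih / h


def _assign_targets(
    targets: list[tuple[int, Box]], config: DetectorConfig
) -> list[tuple[int, int, int, int, Box]]:
    """Pick (scale, anchor, cell) per target by anchor-shape IoU.

    A taken slot falls through to the next-best anchor; an unplaceable target
    is skipped.  Returns (scale_idx, anchor_idx, cell_x, cell_y, box).
    """
    ih, iw = config.input_hw
    occupied: set[tuple] = set()
    placed = []
    for ci, box in targets:
        wh = (box[2] - box[0], box[3] - box[1])
        candidates = sorted(
            (
                (si, ai)
                for si in range(len(config.strides))
                for ai in range(len(config.anchors.per_scale[si]))
            ),
            key=lambda sa: -_wh_iou(wh, config.anchors.per_scale[sa[0]][sa[1]]),
        )
        for si, ai in candidates:
            stride = config.strides[si]
            cx = int((box[0] + box[2]) / 2 / stride)
            cy = int((box[1] + box[3]) / 2 / stride)
            gh, gw = ih // stride, iw // stride
            if not (0 <= cx < gw and 0 <= cy < gh):
                continue
            slot = (si, ai, cx, cy)
            if slot in occupied:
                continue
            occupied.add(slot)
            placed.append((si, ai, cx, cy, ci, box))
            break
    return placed


def _ciou_grad(pred: Box, target: Box, eps: float = 1e-2) -> np.ndarray:
    """d(1 - CIoU)/d(bx, by, bw, bh) by central differences."""
    bx, by = (pred[0] + pred[2]) / 2, (pred[1] + pred[3]) / 2
    bw, bh = pred[2] - pred[0], pred[3] - pred[1]

    def loss(p):
        x, y, w, h = p
        w, h = max(w, 1e-3), max(h, 1e-3)
        return 1.0 - ciou((x - w / 2, y - h / 2, x + w / 2, y + h / 2), target)

    base = np.array([bx, by, bw, bh], dtype=np.float64)
    g = np.zeros(4)
    for i in range(4):
        hi, lo = base.copy(), base.copy()
        hi[i] += eps
        lo[i] -= eps
        g[i] = (loss(hi) - loss(lo)) / (2 * eps)
    return g


def _batch_loss_and_grads(
    model: YoloDetector,
    x: np.ndarray,
    batch_targets: list[list[tuple[int, Box]]],
    config: DetectorConfig,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Forward pass + loss; returns (loss, grad_head3, grad_head4)."""
    nc = len(config.class_names)
    h3, h4 = model.forward(x, train=True)
    heads = [h3, h4]
    grads = [np.zeros_like(h3), np.zeros_like(h4)]
    n = x.shape[0]
    total = 0.0
    n_pos = 0
    for si, (head, stride) in enumerate(zip(heads, config.strides)):
        a = len(config.anchors.per_scale[si])
        _, ch, gh, gw = head.shape
        out = head.reshape(n, a, 5 + nc, gh, gw)
        obj_logits = out[:, :, 4]
        obj_t = np.zeros_like(obj_logits)
        obj_w = np.ones_like(obj_logits)
        # positives: per image, fill targets assigned to this scale
        for bi in range(n):
            for psi, ai, cx, cy, ci, box in batch_targets[bi]:
                if psi != si:
                    continue
                n_pos += 1
                anchor = config.anchors.per_scale[si][ai]
                obj_t[bi, ai, cy, cx] = 1.0
                obj_w[bi, ai, cy, cx] = config.obj_pos_weight
                # class BCE at the positive slot
                cls_logits = out[bi, ai, 5:, cy, cx]
                cls_t = np.zeros(nc, dtype=np.float32)
                cls_t[ci] = 1.0
                closs, cgrad = nn.bce_with_logits(cls_logits, cls_t)
                total += closs
                grads[si].reshape(n, a, 5 + nc, gh, gw)[bi, ai, 5:, cy, cx] += cgrad
                # CIoU box loss at the positive slot
                t_xywh = out[bi, ai, 0:4, cy, cx]
                sx_ = nn.sigmoid(t_xywh[0:2])
                bx = (float(sx_[0]) + cx) * stride
                by = (float(sx_[1]) + cy) * stride
                bw = anchor[0] * float(np.exp(np.clip(t_xywh[2], -8, 8)))
                bh = anchor[1] * float(np.exp(np.clip(t_xywh[3], -8, 8)))
                pred = (bx - bw / 2, by - bh / 2, bx + bw / 2, by + bh / 2)
                total += config.box_weight * (1.0 - ciou(pred, box))
                g_xywh = _ciou_grad(pred, box) * config.box_weight
                # chain rule through the decode map
                gt = np.zeros(4, dtype=np.float32)
                gt[0] = g_xywh[0] * stride * float(sx_[0] * (1 - sx_[0]))
                gt[1] = g_xywh[1] * stride * float(sx_[1] * (1 - sx_[1]))
                gt[2] = g_xywh[2] * bw
                gt[3] = g_xywh[3] * bh
                grads[si].reshape(n, a, 5 + nc, gh, gw)[bi, ai, 0:4, cy, cx] += gt
        oloss, ograd = nn.bce_with_logits(obj_logits, obj_t, weights=obj_w)
        total += oloss
        grads[si].reshape(n, a, 5 + nc, gh, gw)[:, :, 4] += ograd
    denom = max(n_pos, 1)
    return total / denom, grads[0] / denom, grads[1] / denom


def train_detector(
    model: YoloDetector,
    samples: Sequence[tuple[np.ndarray, list[tuple[int, Box]]]],
    config: DetectorConfig | None = None,
) -> tuple[YoloDetector, list[float]]:
    """Fit on (crop image, [(class_id, box in crop coords), ...]) samples.

    Crops are resized to ``config.input_hw`` with their boxes rescaled; the
    loss is CIoU (boxes) + BCE (objectness, classes), optimized with Adam.
    Returns the model and the per-epoch mean loss history.
    """
    cfg = config or model.config
    cfg.validate()
    if len(samples) == 0:
        raise EmptyDataset("no training samples")
    xs, per_sample_targets = [], []
    for crop, targets in samples:
        img, sx, sy = _resize_crop(crop, cfg.input_hw)
        xs.append(img[None])
        scaled = [
            (ci, (b[0] * sx, b[1] * sy, b[2] * sx, b[3] * sy)) for ci, b in targets
        ]
        per_sample_targets.append(_assign_targets(scaled, cfg))
    x_all = np.stack(xs)
    rng = np.random.default_rng(cfg.seed + 1)
    opt = nn.Adam(model.params, lr=cfg.learning_rate)
    history: list[float] = []
    n = len(samples)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            opt.zero_grad()
            loss, g3, g4 = _batch_loss_and_grads(
                model, x_all[idx], [per_sample_targets[i] for i in idx], cfg
            )
            if not np.isfinite(loss):
                raise NonFiniteLoss(f"loss {loss} at epoch {epoch}")
            model.backward(g3, g4)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return model, history


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def detect(
    model: YoloDetector, crop: np.ndarray, config: DetectorConfig | None = None
) -> list[Detection]:
    """Decode, threshold on objectness x class probability, clip, NMS."""
    cfg = config or model.config
    img, sx, sy = _resize_crop(crop, cfg.input_hw)
    h3, h4 = model.forward(img[None, None], train=False)
    nc = len(cfg.class_names)
    h, w = crop.shape
    candidates: list[Detection] = []
    for head, stride, anchors in zip((h3, h4), cfg.strides, cfg.anchors.per_scale):
        dec = decode_head(head, stride, anchors, nc)
        scores = dec["obj"][0][..., None] * dec["cls"][0]  # (A, gh, gw, C)
        keep = np.argwhere(scores > cfg.confidence_threshold)
        for ai, gy, gx, ci in keep:
            b = dec["boxes"][0, ai, gy, gx]
            x0 = min(max(b[0] / sx, 0.0), w)
            y0 = min(max(b[1] / sy, 0.0), h)
            x1 = min(max(b[2] / sx, 0.0), w)
            y1 = min(max(b[3] / sy, 0.0), h)
            if x1 - x0 <= 0 or y1 - y0 <= 0:
                continue
            candidates.append(
                Detection(
                    box=(float(x0), float(y0), float(x1), float(y1)),
                    class_name=cfg.class_names[ci],
                    score=float(scores[ai, gy, gx, ci]),
                )
            )
    return nms(candidates, cfg.nms_iou)


@dataclass
class CropGeometry:
    """What keypoint assignment needs to know about a crop."""

    width: int
    height: int
    mesial_side: str  # "left" or "right"


def assign_keypoints(
    detections: Sequence[Detection], crop_geometry: CropGeometry
) -> tuple[KeypointSet, bool, bool]:
    """Detections -> a labelled six-point set plus lesion flags.

    CEJ and crest detections are split by the crop's vertical midline (the
    best-scoring candidate on each side wins), so each side's crest is paired
    with its own CEJ; the two sides map to mesial/distal through the crop's
    declared mesial side.  A single apex detection serves both sides (the
    unirooted case); apex pairs are ordered by x.  If one side lacks a point,
    the complete side's full CEJ-crest-apex triple is mirrored onto it, so
    staging rests on the measurable side alone.  Lesion flags are true iff
    any surviving lesion-class detection exists.

    Raises
    ------
    IncompleteDetection
        If some role cannot be filled on either side; such a tooth is not
        staged.
    """
    by_role: dict[str, list[Detection]] = {r: [] for r in KEYPOINT_CLASSES}
    for d in detections:
        if d.class_name in by_role:
            by_role[d.class_name].append(d)
    missing = [r for r, ds in by_role.items() if not ds]
    if missing:
        raise IncompleteDetection(missing)

    midline = crop_geometry.width / 2.0
    sides: dict[str, dict[str, Point2D | None]] = {"left": {}, "right": {}}
    unirooted = False
    for role in ("cej", "crest"):
        best: dict[str, Detection | None] = {"left": None, "right": None}
        for d in by_role[role]:
            key = "left" if box_center(d.box).x < midline else "right"
            if best[key] is None or d.score > best[key].score:
                best[key] = d
        for key in ("left", "right"):
            sides[key][role] = box_center(best[key].box) if best[key] else None
    apexes = sorted(by_role["apex"], key=lambda d: -d.score)[:2]
    if len(apexes) == 1:
        unirooted = True
        sides["left"]["apex"] = sides["right"]["apex"] = box_center(apexes[0].box)
    else:
        pl, pr = sorted((box_center(d.box) for d in apexes), key=lambda p: p.x)
        sides["left"]["apex"], sides["right"]["apex"] = pl, pr

    complete = [k for k in ("left", "right") if all(sides[k].get(r) for r in KEYPOINT_CLASSES)]
    if not complete:
        still_missing = sorted(
            {r for k in ("left", "right") for r in KEYPOINT_CLASSES if not sides[k].get(r)}
        )
        raise IncompleteDetection(still_missing)
    for k in ("left", "right"):
        if k not in complete:
            other = complete[0]
            sides[k] = dict(sides[other])

    if crop_geometry.mesial_side == "right":
        mes, dis = sides["right"], sides["left"]
    else:
        mes, dis = sides["left"], sides["right"]
    kp = KeypointSet(
        m1=mes["cej"], m2=mes["crest"], m3=mes["apex"],
        d1=dis["cej"], d2=dis["crest"], d3=dis["apex"],
        unirooted=unirooted,
    )
    vertical = any(d.class_name == "vertical_lesion" for d in detections)
    furcation = any(d.class_name == "furcation_lesion" for d in detections)
    return kp, vertical, furcation


# ---------------------------------------------------------------------------
# Checkpoints / export
# ---------------------------------------------------------------------------

def save_checkpoint(model: YoloDetector, directory: str | Path) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    cfg = asdict(model.config)
    cfg["anchors"] = model.config.anchors.per_scale
    (d / "config.json").write_text(json.dumps(cfg, indent=1))
    np.savez(d / "weights.npz", **{f"p{i}": p.value for i, p in enumerate(model.params)})
    return d


def load_checkpoint(directory: str | Path) -> YoloDetector:
    d = Path(directory)
    raw = json.loads((d / "config.json").read_text())
    raw["anchors"] = AnchorSet([[tuple(a) for a in sc] for sc in raw["anchors"]])
    raw["input_hw"] = tuple(raw["input_hw"])
    raw["strides"] = tuple(raw["strides"])
    raw["class_names"] = tuple(raw["class_names"])
    model = YoloDetector(DetectorConfig(**raw))
    with np.load(d / "weights.npz") as data:
        for i, p in enumerate(model.params):
            p.value[...] = data[f"p{i}"]
    return model


def detections_to_dicts(detections: Sequence[Detection]) -> list[dict]:
    """Detections in the annotation JSON dialect, with an added score field."""
    return [
        {"class": d.class_name, "box": [float(v) for v in d.box], "score": d.score}
        for d in detections
    ]
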
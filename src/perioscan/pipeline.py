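"""Dataset split, 4x flip augmentation with label remapping, and the
end-to-end staging pipeline.

The dataset is split 80/20 into training and test *before* augmentation;
only training images are augmented.  Augmentation emits four variants per
image -- identity, horizontal flip, vertical flip and 180-degree rotation
(= both flips) -- which is the unique involution set of size four closed
under composition, and remaps every keypoint, box and mask consistently.  A
horizontal flip swaps the recorded mesial/distal side orientation and a
vertical flip the jaw (up/down) orientation; stages are untouched since
rigid transforms preserve distance ratios.

The full pipeline composes the two stages: segment the panorama into tooth
crops, detect keypoints and lesions per crop, map detections back through
the crop offset, compute PBL% and assign the stage.  A tooth whose
detections are incomplete is reported separately, never staged, and never
aborts the scene.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
from PIL import Image

from .detector import (
    CropGeometry,
    DetectorConfig,
    IncompleteDetection,
    YoloDetector,
    assign_keypoints,
    detect,
    targets_from_annotation,
)
from .metrics import ConfusionMatrix, classification_metrics, confusion_matrix
from .panorasim import SceneGroundTruth, ToothGroundTruth
from .pbl_core import (
    KeypointSet,
    Point2D,
    StagedTooth,
    ToothAnnotation,
    load_annotations,
    save_annotations,
    stage_tooth,
)
from .segmenter import SegmenterConfig, ToothInstance, UNetSegmenter, crop_tooth, segment_and_crop


class BadFraction(ValueError):
    pass


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

@dataclass
class DatasetManifest:
    """Table of (image, annotation, mask, split) records, rooted at a directory."""

    root: Path
    records: list[dict] = field(default_factory=list)
    seed: int | None = None

    def paths(self, record: dict) -> tuple[Path, Path, Path]:
        return (
            self.root / record["image"],
            self.root / record["annotation"],
            self.root / record["mask"],
        )

    def subset(self, split: str) -> list[dict]:
        return [r for r in self.records if r["split"] == split]

    def save(self, path: str | Path | None = None) -> Path:
        p = Path(path) if path else self.root / "manifest.json"
        p.write_text(json.dumps({"seed": self.seed, "records": self.records}, indent=1))
        return p


def load_manifest(path: str | Path) -> DatasetManifest:
    p = Path(path)
    doc = json.loads(p.read_text())
    return DatasetManifest(root=p.parent, records=doc["records"], seed=doc.get("seed"))


def split_dataset(
    manifest: DatasetManifest, train_fraction: float = 0.8, seed: int = 0
) -> DatasetManifest:
    """Assign floor(n * fraction) records to train, the rest to test.

    The assignment is a seeded shuffle; it happens before (and is unaffected
    by) augmentation.  Fractions without both a train and a test item are
    rejected.
    """
    n = len(manifest.records)
    if n < 2:
        raise BadFraction("need at least two records to split")
    n_train = int(np.floor(n * train_fraction))
    if n_train < 1 or n_train >= n:
        raise BadFraction(f"fraction {train_fraction} leaves an empty split for n={n}")
    order = np.random.default_rng(seed).permutation(n)
    train_ids = set(order[:n_train].tolist())
    records = [
        {**r, "split": "train" if i in train_ids else "test"}
        for i, r in enumerate(manifest.records)
    ]
    return DatasetManifest(root=manifest.root, records=records, seed=manifest.seed)


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

class AugmentTransform(str, Enum):
    identity = "identity"
    hflip = "hflip"
    vflip = "vflip"
    rot180 = "rot180"


_SWAP_SIDE = {"left": "right", "right": "left"}
_SWAP_ORIENT = {"up": "down", "down": "up"}


def _transform_point(p: Point2D, t: AugmentTransform, h: int, w: int) -> Point2D:
    x, y = p.x, p.y
    if t in (AugmentTransform.hflip, AugmentTransform.rot180):
        x = (w - 1) - x
    if t in (AugmentTransform.vflip, AugmentTransform.rot180):
        y = (h - 1) - y
    return Point2D(x, y)


def _transform_box(box, t: AugmentTransform, h: int, w: int):
    x0, y0, x1, y1 = box
    if t in (AugmentTransform.hflip, AugmentTransform.rot180):
        x0, x1 = w - x1, w - x0
    if t in (AugmentTransform.vflip, AugmentTransform.rot180):
        y0, y1 = h - y1, h - y0
    return [x0, y0, x1, y1]


def _transform_pixels(a: np.ndarray, t: AugmentTransform) -> np.ndarray:
    if t in (AugmentTransform.hflip, AugmentTransform.rot180):
        a = a[:, ::-1]
    if t in (AugmentTransform.vflip, AugmentTransform.rot180):
        a = a[::-1, :]
    return np.ascontiguousarray(a)


def apply_transform(
    image: np.ndarray,
    teeth: list[ToothAnnotation],
    t: AugmentTransform,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, list[ToothAnnotation], np.ndarray | None]:
    """Transform pixels and every annotation coordinate consistently.

    Points map pixel-to-pixel (x -> W-1-x under a horizontal flip); half-open
    boxes map edge-to-edge ([x0, x1) -> [W-x1, W-x0)).  The mesial-side flag
    flips with a horizontal flip, the jaw orientation with a vertical flip;
    stage labels are preserved.
    """
    h, w = image.shape[:2]
    new_teeth = []
    for ann in teeth:
        pts = {
            name: _transform_point(p, t, h, w)
            for name, p in ann.keypoints.points().items()
        }
        kp = KeypointSet(tooth_id=ann.tooth_id, unirooted=ann.unirooted, **pts)
        side = ann.mesial_side
        orient = ann.orientation
        if t in (AugmentTransform.hflip, AugmentTransform.rot180):
            side = _SWAP_SIDE[side]
        if t in (AugmentTransform.vflip, AugmentTransform.rot180):
            orient = _SWAP_ORIENT[orient]
        new_teeth.append(
            ToothAnnotation(
                tooth_id=ann.tooth_id,
                keypoints=kp,
                stage=ann.stage,
                unirooted=ann.unirooted,
                mesial_side=side,
                orientation=orient,
                lesion_boxes=[
                    {"class": b["class"], "box": _transform_box(b["box"], t, h, w)}
                    for b in ann.lesion_boxes
                ],
            )
        )
    new_mask = _transform_pixels(mask, t) if mask is not None else None
    return _transform_pixels(image, t), new_teeth, new_mask


_AUG_SUFFIX = {
    AugmentTransform.identity: "id",
    AugmentTransform.hflip: "hf",
    AugmentTransform.vflip: "vf",
    AugmentTransform.rot180: "rr",
}


def augment_dataset(manifest: DatasetManifest) -> DatasetManifest:
    """Expand the training split to exactly 4x with the flip family.

    Writes the variants under ``augmented/`` beside the originals; test
    records pass through untouched.
    """
    out_root = manifest.root
    for sub in ("augmented/images", "augmented/annotations", "augmented/masks"):
        (out_root / sub).mkdir(parents=True, exist_ok=True)
    new_records: list[dict] = []
    for rec in manifest.records:
        if rec["split"] != "train":
            new_records.append(dict(rec))
            continue
        img_p, ann_p, mask_p = manifest.paths(rec)
        image = np.asarray(Image.open(img_p))
        mask = np.asarray(Image.open(mask_p))
        teeth, size = load_annotations(ann_p)
        stem = img_p.stem
        for t in AugmentTransform:
            im2, teeth2, mask2 = apply_transform(image, teeth, t, mask)
            suffix = _AUG_SUFFIX[t]
            rel_img = f"augmented/images/{stem}_{suffix}.png"
            rel_ann = f"augmented/annotations/{stem}_{suffix}.json"
            rel_mask = f"augmented/masks/{stem}_{suffix}.png"
            Image.fromarray(im2).save(out_root / rel_img)
            Image.fromarray(mask2).save(out_root / rel_mask)
            save_annotations(out_root / rel_ann, teeth2, size)
            new_records.append(
                {
                    "image": rel_img,
                    "annotation": rel_ann,
                    "mask": rel_mask,
                    "split": "train",
                    "n_teeth": rec["n_teeth"],
                }
            )
    return DatasetManifest(root=out_root, records=new_records, seed=manifest.seed)


# ---------------------------------------------------------------------------
# Training-data assembly from a manifest
# ---------------------------------------------------------------------------

def scene_ground_truth(manifest: DatasetManifest, record: dict) -> SceneGroundTruth:
    """Rebuild a SceneGroundTruth from the stored annotation + label map."""
    _, ann_p, mask_p = manifest.paths(record)
    teeth, (h, w) = load_annotations(ann_p)
    label_map = np.asarray(Image.open(mask_p))
    gt_teeth = [
        ToothGroundTruth(
            tooth_id=ann.tooth_id,
            mask=label_map == k,
            keypoints=ann.keypoints,
            stage=ann.stage,
            lesion_boxes=ann.lesion_boxes,
            mesial_side=ann.mesial_side,
            orientation=ann.orientation,
        )
        for k, ann in enumerate(teeth, start=1)
    ]
    return SceneGroundTruth(image_size=(h, w), teeth=gt_teeth)


def segmentation_pairs(
    manifest: DatasetManifest, split: str = "train", downscale: int = 2
) -> list[tuple[np.ndarray, np.ndarray]]:
    """(image, union-of-teeth mask) pairs for segmenter training.

    Pairs are subsampled by the segmenter's working ``downscale`` factor so
    training matches inference resolution.
    """
    s = max(1, downscale)
    pairs = []
    for rec in manifest.subset(split):
        img_p, _, mask_p = manifest.paths(rec)
        image = np.asarray(Image.open(img_p))
        label_map = np.asarray(Image.open(mask_p))
        pairs.append((image[::s, ::s], label_map[::s, ::s] > 0))
    return pairs


def instance_from_mask(mask: np.ndarray) -> ToothInstance:
    """A ToothInstance wrapping a reference (ground-truth) tooth mask."""
    ys, xs = np.nonzero(mask)
    return ToothInstance(
        contour=[],
        mask=mask,
        bbox=(int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1),
        area=int(mask.sum()),
    )


def detection_samples(
    manifest: DatasetManifest,
    split: str = "train",
    margin: int = 20,
    keypoint_box_side: float = 12.0,
) -> list[tuple[np.ndarray, list]]:
    """Per-tooth (crop, targets) samples cut with the reference masks."""
    samples = []
    for rec in manifest.subset(split):
        img_p, _, _ = manifest.paths(rec)
        image = np.asarray(Image.open(img_p))
        gt = scene_ground_truth(manifest, rec)
        for t in gt.teeth:
            crop = crop_tooth(image, instance_from_mask(t.mask), margin=margin)
            targets = targets_from_annotation(
                t.to_annotation(), crop.offset, crop.pixels.shape, keypoint_box_side
            )
            samples.append((crop.pixels, targets))
    return samples


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    staged: list[StagedTooth]
    incomplete: list[dict]  # {"offset": Point2D, "missing": [roles]}


def run_pipeline(
    image: np.ndarray,
    seg_model: UNetSegmenter,
    det_model: YoloDetector,
    seg_config: SegmenterConfig | None = None,
    det_config: DetectorConfig | None = None,
) -> PipelineResult:
    """Segment -> crop -> detect -> assign keypoints -> compute PBL -> stage.

    Keypoints are mapped to panorama coordinates through the crop offset
    before staging (the offset cancels in the distance ratios, so staging is
    identical in either frame).  The mesial side of each crop follows the
    arch-midline rule: teeth left of the panorama midline have their mesial
    surface on the right.
    """
    scfg = seg_config or seg_model.config
    w_mid = image.shape[1] / 2.0
    crops = segment_and_crop(seg_model, image, scfg)
    staged: list[StagedTooth] = []
    incomplete: list[dict] = []
    for idx, crop in enumerate(crops):
        h, w = crop.pixels.shape
        center_x = crop.offset.x + w / 2.0
        mesial_side = "right" if center_x < w_mid else "left"
        dets = detect(det_model, crop.pixels, det_config)
        geom = CropGeometry(width=w, height=h, mesial_side=mesial_side)
        try:
            kp, vertical, furcation = assign_keypoints(dets, geom)
        except IncompleteDetection as e:
            incomplete.append({"offset": crop.offset, "missing": e.missing_roles})
            continue
        panorama_kp = KeypointSet(
            tooth_id=f"t{idx}",
            unirooted=kp.unirooted,
            **{
                name: Point2D(p.x + crop.offset.x, p.y + crop.offset.y)
                for name, p in kp.points().items()
            },
        )
        staged.append(stage_tooth(panorama_kp, vertical=vertical, furcation=furcation))
    return PipelineResult(staged=staged, incomplete=incomplete)


def _centroid(kp: KeypointSet) -> tuple[float, float]:
    pts = list(kp.points().values())
    return (float(np.mean([p.x for p in pts])), float(np.mean([p.y for p in pts])))


def evaluate_staging(
    manifest: DatasetManifest,
    seg_model: UNetSegmenter,
    det_model: YoloDetector,
    split: str = "test",
    det_config: DetectorConfig | None = None,
) -> dict:
    """Stage every test-scene tooth end-to-end and score against the reference.

    Each predicted tooth is matched to the nearest reference tooth by
    keypoint centroid (one-to-one, nearest first).  Reference teeth with no
    surviving prediction count as errors in ``accuracy``; the confusion
    matrix covers matched teeth only.
    """
    refs, preds = [], []
    n_ref_total, n_unmatched, n_incomplete = 0, 0, 0
    for rec in manifest.subset(split):
        img_p, _, _ = manifest.paths(rec)
        image = np.asarray(Image.open(img_p))
        gt = scene_ground_truth(manifest, rec)
        result = run_pipeline(image, seg_model, det_model, det_config=det_config)
        n_ref_total += len(gt.teeth)
        n_incomplete += len(result.incomplete)
        gt_cents = [_centroid(t.keypoints) for t in gt.teeth]
        taken: set[int] = set()
        pairs = []
        for st in result.staged:
            c = _centroid(st.keypoints)
            dists = [
                (np.hypot(c[0] - gc[0], c[1] - gc[1]), gi)
                for gi, gc in enumerate(gt_cents)
                if gi not in taken
            ]
            if not dists:
                continue
            d, gi = min(dists)
            taken.add(gi)
            pairs.append((gi, st, d))
        for gi, st, _d in pairs:
            refs.append(gt.teeth[gi].stage)
            preds.append(st.stage)
        n_unmatched += len(gt.teeth) - len(pairs)
    cm = confusion_matrix(refs, preds)
    n_correct = int(np.trace(cm.counts))
    return {
        "confusion_matrix": cm,
        "report": classification_metrics(cm),
        "accuracy": n_correct / n_ref_total if n_ref_total else None,
        "n_reference_teeth": n_ref_total,
        "n_matched": len(refs),
        "n_unmatched_reference": n_unmatched,
        "n_incomplete": n_incomplete,
    }


def report_to_csv(cm: ConfusionMatrix, path: str | Path) -> None:
    """Per-class metric rows (plus macro total) as a CSV table."""
    import pandas as pd

    rep = classification_metrics(cm)
    rows = []
    for label, m in list(rep.per_class.items()) + [("Total", rep.overall)]:
        name = getattr(label, "value", label)
        rows.append(
            {
                "class": name,
                "accuracy": m.accuracy,
                "precision": m.precision,
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "f1": m.f1,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
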
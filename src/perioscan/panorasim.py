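"""Synthetic panoramic-radiograph-like scenes with exact ground truth.

Real panoramic radiographs of periodontitis patients are not publicly
distributable, so every stage of the pipeline is exercised on a parametric
stand-in: a dental arch of simplified teeth (bright crown + one- or two-rooted
root polygons) over a darker jaw band, with an alveolar bone margin rendered
as a bright wedge along each root flank.  The crest height along the
CEJ->apex segment is the controlled quantity: its fraction of root length IS
the per-side bone loss, so every keypoint, stage label and lesion box is known
analytically from the generating parameters -- never recovered by detection.

Geometry is deliberately schematic (polygons and ellipses, no projection
physics, ghost shadows or spine overlap): the pipeline's contracts are under
test, not radiographic realism.  Mesial/distal is defined as toward/away from
the arch midline and recorded per tooth, so side assignment is unambiguous.

Scale defaults: a 512x256 (width x height) 8-bit grayscale canvas with two
rows of teeth (maxilla crowns pointing down, mandible crowns up).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import polygon as draw_polygon

from .pbl_core import (
    KeypointSet,
    Point2D,
    Stage,
    ToothAnnotation,
    assign_stage,
    compute_pbl,
    save_annotations,
)


class UnknownStage(ValueError):
    pass


class CanvasOverflow(ValueError):
    pass


class IOFailure(OSError):
    pass


#: Sampling interval of the staging-relevant bone fraction per target stage.
STAGE_INTERVALS = {
    Stage.I: (0.0, 0.149),
    Stage.II: (0.15, 0.33),
    Stage.III_IV: (0.335, 0.9),
}


@dataclass(frozen=True)
class VerticalDefect:
    """A localized angular (vertical) bone defect on one root flank.

    ``depth_fraction`` is the extra crest drop at the flank, as a fraction of
    root length, relative to the flat bone level further from the tooth.
    """

    side: str  # "mesial" or "distal"
    depth_fraction: float
    width_px: float


@dataclass
class ToothSpec:
    """Full parametric description of one synthetic tooth."""

    position_index: int
    center: Point2D  # midpoint of the CEJ line
    crown_size: float  # crown height, px
    root_length: float  # CEJ to apex, px
    n_roots: int
    orientation: str  # "up": crown up / roots down (mandible); "down": maxilla
    bone_fraction_mesial: float  # flat bone level, fraction of root length
    bone_fraction_distal: float
    mesial_side: str = "left"  # which image side faces the arch midline
    vertical_defect: VerticalDefect | None = None
    furcation_lesion: bool = False
    crown_width: float = 34.0
    root_width: float = 22.0
    crown_intensity: float = 235.0
    root_intensity: float = 200.0
    bone_intensity: float = 140.0

    def __post_init__(self) -> None:
        if self.n_roots not in (1, 2):
            raise ValueError("n_roots must be 1 or 2")
        if self.n_roots == 1 and self.furcation_lesion:
            raise ValueError("furcation lesions require two roots")
        for f in (self.bone_fraction_mesial, self.bone_fraction_distal):
            if not (0.0 <= f <= 1.0):
                raise ValueError("bone fractions must lie in [0, 1]")

    # -- analytic geometry ---------------------------------------------------

    @property
    def root_dir(self) -> int:
        """+1 if roots point toward larger y (mandible), else -1."""
        return -1 if self.orientation == "down" else 1

    def effective_fraction(self, side: str) -> float:
        f = self.bone_fraction_mesial if side == "mesial" else self.bone_fraction_distal
        if self.vertical_defect is not None and self.vertical_defect.side == side:
            f = min(f + self.vertical_defect.depth_fraction, 0.98)
        return f

    def keypoints(self) -> KeypointSet:
        """The six landmarks implied by the spec, exactly.

        CEJ points sit at the root corners on the CEJ line; apices at the
        (outer) root-tip corners, coincident at the tooth axis for single
        roots; each crest lies on its CEJ->apex segment at the effective
        bone fraction, so the three points of a side are always collinear.
        """
        cx, cy = self.center.x, self.center.y
        s = 1.0 if self.mesial_side == "right" else -1.0
        tip_y = cy + self.root_dir * self.root_length
        m1 = Point2D(cx + s * self.root_width / 2, cy)
        d1 = Point2D(cx - s * self.root_width / 2, cy)
        if self.n_roots == 1:
            m3 = d3 = Point2D(cx, tip_y)
        else:
            spread = self.root_spread
            m3 = Point2D(cx + s * spread, tip_y)
            d3 = Point2D(cx - s * spread, tip_y)
        fm = self.effective_fraction("mesial")
        fd = self.effective_fraction("distal")
        m2 = Point2D(m1.x + fm * (m3.x - m1.x), m1.y + fm * (m3.y - m1.y))
        d2 = Point2D(d1.x + fd * (d3.x - d1.x), d1.y + fd * (d3.y - d1.y))
        return KeypointSet(
            m1=m1, m2=m2, m3=m3, d1=d1, d2=d2, d3=d3,
            tooth_id=f"t{self.position_index}", unirooted=self.n_roots == 1,
        )

    @property
    def root_spread(self) -> float:
        """Half-distance between the two root-tip outer corners."""
        return self.root_width * 0.55


@dataclass
class ToothGroundTruth:
    tooth_id: str
    mask: np.ndarray  # boolean, full-canvas
    keypoints: KeypointSet
    stage: Stage
    lesion_boxes: list[dict]  # {"class": "vertical"|"furcation", "box": [...]}
    mesial_side: str
    orientation: str

    def to_annotation(self) -> ToothAnnotation:
        return ToothAnnotation(
            tooth_id=self.tooth_id,
            keypoints=self.keypoints,
            stage=self.stage,
            unirooted=self.keypoints.unirooted,
            mesial_side=self.mesial_side,
            orientation=self.orientation,
            lesion_boxes=self.lesion_boxes,
        )


@dataclass
class SceneGroundTruth:
    image_size: tuple[int, int]  # (height, width)
    teeth: list[ToothGroundTruth]


@dataclass
class SceneConfig:
    """Canvas layout and rendering parameters.

    Vertical positions and root lengths scale with the canvas height so the
    same config renders consistently at reduced sizes.
    """

    height: int = 256
    width: int = 512
    teeth_per_row: int = 6
    margin_x: float = 26.0
    cej_top_rel: float = 0.40  # maxillary CEJ line, fraction of height
    cej_bottom_rel: float = 0.60  # mandibular CEJ line
    root_length_rel: tuple[float, float] = (0.21, 0.285)
    crown_height_rel: tuple[float, float] = (0.06, 0.085)
    crown_width_frac: tuple[float, float] = (0.40, 0.52)  # of tooth spacing
    root_width_frac: tuple[float, float] = (0.58, 0.70)  # of crown width
    background_intensity: float = 28.0
    band_intensity: float = 70.0
    blur_sigma: float = 0.8
    noise_sd: float = 5.0
    min_area: int = 30
    center_jitter: float = 2.0

    def easy(self) -> "SceneConfig":
        """The clean regime: no blur, no noise, no jitter."""
        return replace(self, blur_sigma=0.0, noise_sd=0.0, center_jitter=0.0)

    @property
    def spacing(self) -> float:
        return (self.width - 2 * self.margin_x) / self.teeth_per_row


# ---------------------------------------------------------------------------
# Tooth sampling
# ---------------------------------------------------------------------------

def sample_tooth_spec(
    rng: np.random.Generator,
    position_index: int,
    stage_target: Stage,
    lesion_rates: tuple[float, float] = (0.15, 0.25),
    scene: SceneConfig | None = None,
) -> ToothSpec:
    """Draw one tooth's parameters for a requested stage.

    Bone fractions are uniform on the stage's interval (I: [0, 0.15),
    II: [0.15, 0.33], III/IV: (0.33, 0.9]).  ``lesion_rates`` is
    (vertical, furcation); a vertical defect deepens one crest locally, and
    its depth is folded into the interval draw so the staging-relevant
    maximum -- hence the recomputed stage -- still matches ``stage_target``.
    Deterministic given the generator state.
    """
    if scene is None:
        scene = SceneConfig()
    if stage_target not in STAGE_INTERVALS:
        raise UnknownStage(str(stage_target))
    v_rate, f_rate = lesion_rates
    if not (0.0 <= v_rate <= 1.0 and 0.0 <= f_rate <= 1.0):
        raise ValueError("lesion rates must lie in [0, 1]")

    n_row = scene.teeth_per_row
    row = position_index // n_row  # 0 = maxilla, 1 = mandible
    col = position_index % n_row
    orientation = "down" if row == 0 else "up"
    cej_y = scene.height * (scene.cej_top_rel if row == 0 else scene.cej_bottom_rel)
    cx = scene.margin_x + (col + 0.5) * scene.spacing
    if scene.center_jitter > 0:
        cx += rng.uniform(-scene.center_jitter, scene.center_jitter)
        cej_y += rng.uniform(-scene.center_jitter, scene.center_jitter)
    mesial_side = "right" if cx < scene.width / 2 else "left"

    crown_w = scene.spacing * rng.uniform(*scene.crown_width_frac)
    root_w = crown_w * rng.uniform(*scene.root_width_frac)
    root_len = scene.height * rng.uniform(*scene.root_length_rel)
    crown_h = scene.height * rng.uniform(*scene.crown_height_rel)
    n_roots = 2 if rng.random() < 0.5 else 1

    lo, hi = STAGE_INTERVALS[stage_target]
    f_mesial = float(rng.uniform(lo, hi))
    f_distal = float(rng.uniform(lo, hi))

    defect = None
    if rng.random() < v_rate:
        side = "mesial" if rng.random() < 0.5 else "distal"
        depth = float(rng.uniform(0.08, 0.20))
        # keep the effective (deepened) crest inside the target interval
        eff = f_mesial if side == "mesial" else f_distal
        base = max(eff - depth, 0.0)
        depth = eff - base
        if depth > 1e-6:
            defect = VerticalDefect(
                side=side, depth_fraction=depth,
                width_px=float(rng.uniform(0.25, 0.45) * root_w),
            )
            if side == "mesial":
                f_mesial = base
            else:
                f_distal = base
    furcation = bool(n_roots == 2 and rng.random() < f_rate)

    return ToothSpec(
        position_index=position_index,
        center=Point2D(cx, cej_y),
        crown_size=crown_h,
        root_length=root_len,
        n_roots=n_roots,
        orientation=orientation,
        bone_fraction_mesial=f_mesial,
        bone_fraction_distal=f_distal,
        mesial_side=mesial_side,
        vertical_defect=defect,
        furcation_lesion=furcation,
        crown_width=crown_w,
        root_width=root_w,
        crown_intensity=float(rng.uniform(225, 245)),
        root_intensity=float(rng.uniform(190, 210)),
        bone_intensity=float(rng.uniform(130, 150)),
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _fill_polygon(canvas: np.ndarray, xy: Sequence[tuple[float, float]], value: float) -> None:
    xs = np.array([p[0] for p in xy])
    ys = np.array([p[1] for p in xy])
    rr, cc = draw_polygon(ys, xs, shape=canvas.shape)
    canvas[rr, cc] = value


def _tooth_polygons(spec: ToothSpec) -> tuple[list, list]:
    """(crown polygon, root polygon) as (x, y) vertex lists."""
    cx, cy = spec.center.x, spec.center.y
    d = spec.root_dir
    tip_y = cy + d * spec.root_length
    rw2 = spec.root_width / 2
    crown = [
        (cx - spec.crown_width / 2, cy),
        (cx + spec.crown_width / 2, cy),
        (cx + spec.crown_width * 0.38, cy - d * spec.crown_size),
        (cx - spec.crown_width * 0.38, cy - d * spec.crown_size),
    ]
    if spec.n_roots == 1:
        tw = rw2 * 0.4
        root = [
            (cx - rw2, cy), (cx + rw2, cy),
            (cx + tw, tip_y), (cx - tw, tip_y),
        ]
    else:
        sp = spec.root_spread
        inner = sp * 0.45
        fork_y = cy + d * spec.root_length * 0.42
        root = [
            (cx - rw2, cy), (cx + rw2, cy),
            (cx + sp, tip_y), (cx + inner, tip_y),
            (cx, fork_y),
            (cx - inner, tip_y), (cx - sp, tip_y),
        ]
    return crown, root


def _bone_polygon(spec: ToothSpec, kp: KeypointSet, side: str, reach: float) -> list:
    """Bone wedge hugging one root flank; top vertex is exactly the crest point.

    ``reach`` is how far (px) the wedge extends horizontally away from the
    tooth.  A vertical defect on this side turns the near-flank top edge into
    a steep notch down to the crest.
    """
    cej = kp.m1 if side == "mesial" else kp.d1
    crest = kp.m2 if side == "mesial" else kp.d2
    apex = kp.m3 if side == "mesial" else kp.d3
    # outward direction for this side: mesial side faces the arch midline
    if side == "mesial":
        s = 1.0 if spec.mesial_side == "right" else -1.0
    else:
        s = -1.0 if spec.mesial_side == "right" else 1.0
    d = spec.root_dir
    slope = 4.0
    defect = spec.vertical_defect
    if defect is not None and defect.side == side:
        base_f = (spec.bone_fraction_mesial if side == "mesial"
                  else spec.bone_fraction_distal)
        base_pt_y = cej.y + base_f * (apex.y - cej.y)
        return [
            (crest.x, crest.y),
            (apex.x, apex.y),
            (apex.x + s * reach, apex.y),
            (crest.x + s * reach, base_pt_y + d * slope),
            (crest.x + s * defect.width_px, base_pt_y),
        ]
    return [
        (crest.x, crest.y),
        (apex.x, apex.y),
        (apex.x + s * reach, apex.y),
        (crest.x + s * reach, crest.y + d * slope),
    ]


def _lesion_boxes(spec: ToothSpec, kp: KeypointSet, shape: tuple[int, int]) -> list[dict]:
    """Half-open boxes of the rendered lesions, clipped to the canvas."""
    h, w = shape
    boxes: list[dict] = []
    defect = spec.vertical_defect
    if defect is not None:
        cej = kp.m1 if defect.side == "mesial" else kp.d1
        crest = kp.m2 if defect.side == "mesial" else kp.d2
        apex = kp.m3 if defect.side == "mesial" else kp.d3
        base_f = (spec.bone_fraction_mesial if defect.side == "mesial"
                  else spec.bone_fraction_distal)
        y0 = cej.y + base_f * (apex.y - cej.y)
        y1 = crest.y
        if defect.side == "mesial":
            s = 1.0 if spec.mesial_side == "right" else -1.0
        else:
            s = -1.0 if spec.mesial_side == "right" else 1.0
        xs = (crest.x, crest.x + s * defect.width_px)
        pad = 3.0
        box = [min(xs) - pad, min(y0, y1) - pad, max(xs) + pad, max(y0, y1) + pad]
        boxes.append({"class": "vertical", "box": _clip_box(box, h, w)})
    if spec.furcation_lesion:
        cx, cy = spec.center.x, spec.center.y
        d = spec.root_dir
        blob_cy = cy + d * spec.root_length * 0.60
        rx = spec.root_spread * 0.75
        ry = spec.root_length * 0.13
        box = [cx - rx - 2, blob_cy - ry - 2, cx + rx + 2, blob_cy + ry + 2]
        boxes.append({"class": "furcation", "box": _clip_box(box, h, w)})
    return boxes


def _clip_box(box: Sequence[float], h: int, w: int) -> list[float]:
    return [
        float(max(0.0, box[0])), float(max(0.0, box[1])),
        float(min(float(w), box[2])), float(min(float(h), box[3])),
    ]


def render_scene(
    specs: Sequence[ToothSpec], image_params: SceneConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, SceneGroundTruth]:
    """Draw the scene and compute its ground truth analytically.

    Draw order: jaw bands, bone wedges (with any vertical-defect notch),
    tooth polygons, furcation radiolucencies; then Gaussian blur and additive
    Gaussian noise per the config.  Ground truth (masks, keypoints, stage,
    lesion boxes) comes from the specs alone, never from the rendered pixels.
    """
    cfg = image_params or SceneConfig()
    h, w = cfg.height, cfg.width
    canvas = np.full((h, w), cfg.background_intensity, dtype=np.float64)

    # validity: every keypoint must land inside the canvas
    for spec in specs:
        kp = spec.keypoints()
        for name, p in kp.points().items():
            if not (0 <= p.x < w and 0 <= p.y < h):
                raise CanvasOverflow(
                    f"tooth {spec.position_index} keypoint {name} at "
                    f"({p.x:.1f}, {p.y:.1f}) outside {w}x{h} canvas"
                )

    # jaw bands: one per row, spanning CEJ line to beyond the apices
    for cej_rel, d in ((cfg.cej_top_rel, -1), (cfg.cej_bottom_rel, 1)):
        cej_y = cfg.height * cej_rel
        far = cej_y + d * cfg.height * (cfg.root_length_rel[1] + 0.05)
        y0, y1 = sorted((cej_y + d * 2, far))
        _fill_polygon(canvas, [(0, y0), (w, y0), (w, y1), (0, y1)], cfg.band_intensity)

    reach = cfg.spacing / 2
    teeth_gt: list[ToothGroundTruth] = []
    for spec in specs:
        kp = spec.keypoints()
        for side in ("mesial", "distal"):
            _fill_polygon(canvas, _bone_polygon(spec, kp, side, reach), spec.bone_intensity)

    masks = []
    for spec in specs:
        crown, root = _tooth_polygons(spec)
        mask = np.zeros((h, w), dtype=bool)
        for poly, val in ((root, spec.root_intensity), (crown, spec.crown_intensity)):
            xs = np.array([p[0] for p in poly])
            ys = np.array([p[1] for p in poly])
            rr, cc = draw_polygon(ys, xs, shape=(h, w))
            canvas[rr, cc] = val
            mask[rr, cc] = True
        masks.append(mask)

    for spec, mask in zip(specs, masks):
        kp = spec.keypoints()
        if spec.furcation_lesion:
            d = spec.root_dir
            blob_cy = spec.center.y + d * spec.root_length * 0.60
            rr, cc = draw_ellipse(
                blob_cy, spec.center.x,
                spec.root_length * 0.11, spec.root_spread * 0.65, shape=(h, w),
            )
            canvas[rr, cc] = cfg.band_intensity * 0.8
        pbl = compute_pbl(kp)
        teeth_gt.append(
            ToothGroundTruth(
                tooth_id=kp.tooth_id,
                mask=mask,
                keypoints=kp,
                stage=assign_stage(pbl.pbl_max),
                lesion_boxes=_lesion_boxes(spec, kp, (h, w)),
                mesial_side=spec.mesial_side,
                orientation=spec.orientation,
            )
        )

    if cfg.blur_sigma > 0:
        from scipy.ndimage import gaussian_filter

        canvas = gaussian_filter(canvas, cfg.blur_sigma)
    if cfg.noise_sd > 0:
        noise_rng = rng if rng is not None else np.random.default_rng(0)
        canvas = canvas + noise_rng.normal(0.0, cfg.noise_sd, size=canvas.shape)
    image = np.clip(canvas, 0, 255).astype(np.uint8)
    return image, SceneGroundTruth(image_size=(h, w), teeth=teeth_gt)


def verify_ground_truth(
    gt: SceneGroundTruth, min_area: int = 30, max_overlap: float = 0.05
) -> list[str]:
    """Check every scene invariant; an empty list means the scene is clean.

    Checks: keypoints inside the canvas; per-tooth mask area >= ``min_area``;
    unirooted apices coincident; the stored stage equals the stage recomputed
    from the keypoints; pairwise mask overlap below ``max_overlap`` of the
    smaller mask.
    """
    h, w = gt.image_size
    violations: list[str] = []
    for t in gt.teeth:
        for name, p in t.keypoints.points().items():
            if not (0 <= p.x < w and 0 <= p.y < h):
                violations.append(f"OutOfBounds:{t.tooth_id}:{name}")
        if int(t.mask.sum()) < min_area:
            violations.append(f"MaskTooSmall:{t.tooth_id}")
        if t.keypoints.unirooted and t.keypoints.m3 != t.keypoints.d3:
            violations.append(f"ApexMismatch:{t.tooth_id}")
        recomputed = assign_stage(compute_pbl(t.keypoints).pbl_max)
        if recomputed != t.stage:
            violations.append(f"StageMismatch:{t.tooth_id}")
    for i in range(len(gt.teeth)):
        for j in range(i + 1, len(gt.teeth)):
            a, b = gt.teeth[i].mask, gt.teeth[j].mask
            inter = int(np.logical_and(a, b).sum())
            smaller = max(1, min(int(a.sum()), int(b.sum())))
            if inter / smaller > max_overlap:
                violations.append(
                    f"MaskOverlap:{gt.teeth[i].tooth_id}:{gt.teeth[j].tooth_id}"
                )
    return violations


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

@dataclass
class DatasetConfig:
    """What to generate and where."""

    out_dir: str | Path
    n_images: int = 50
    stage_mix: tuple[float, float, float] = (0.5, 0.3, 0.2)  # I, II, III/IV
    lesion_rates: tuple[float, float] = (0.15, 0.25)  # vertical, furcation
    scene: SceneConfig = field(default_factory=SceneConfig)


def _child_rng(seed: int, index: int) -> np.random.Generator:
    """Per-image generator: SeedSequence(root_seed) spawned at key (index,)."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def make_scene(
    rng: np.random.Generator, config: DatasetConfig
) -> tuple[np.ndarray, SceneGroundTruth]:
    """Sample one full scene: per-tooth stage targets from the mix, then render."""
    scene = config.scene
    n_teeth = 2 * scene.teeth_per_row
    mix = np.asarray(config.stage_mix, dtype=np.float64)
    mix = mix / mix.sum()
    stage_ids = rng.choice(3, size=n_teeth, p=mix)
    stages = [list(STAGE_INTERVALS)[i] for i in stage_ids]
    specs = [
        sample_tooth_spec(rng, i, stages[i], config.lesion_rates, scene)
        for i in range(n_teeth)
    ]
    return render_scene(specs, scene, rng=rng)


def generate_dataset(config: DatasetConfig, seed: int) -> Path:
    """Write images, annotations, instance-label masks and a manifest.

    Layout: ``images/scene_NNNN.png``, ``annotations/scene_NNNN.json``,
    ``masks/scene_NNNN.png`` (uint8 label map, 0 = background, k = tooth k),
    and ``manifest.json``.  Image ``i`` uses the child generator spawned at
    key ``(i,)`` from the root seed, so any subset is reproducible.
    """
    out = Path(config.out_dir)
    try:
        for sub in ("images", "annotations", "masks"):
            (out / sub).mkdir(parents=True, exist_ok=True)
    except OSError as e:  # pragma: no cover
        raise IOFailure(str(e)) from e

    records = []
    for i in range(config.n_images):
        rng = _child_rng(seed, i)
        image, gt = make_scene(rng, config)
        stem = f"scene_{i:04d}"
        img_path = out / "images" / f"{stem}.png"
        ann_path = out / "annotations" / f"{stem}.json"
        mask_path = out / "masks" / f"{stem}.png"
        Image.fromarray(image).save(img_path)
        label_map = np.zeros(image.shape, dtype=np.uint8)
        for k, t in enumerate(gt.teeth, start=1):
            label_map[t.mask] = k
        Image.fromarray(label_map).save(mask_path)
        save_annotations(ann_path, [t.to_annotation() for t in gt.teeth], gt.image_size)
        records.append(
            {
                "image": str(img_path.relative_to(out)),
                "annotation": str(ann_path.relative_to(out)),
                "mask": str(mask_path.relative_to(out)),
                "split": "",
                "n_teeth": len(gt.teeth),
            }
        )
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps({"seed": seed, "records": records}, indent=1))
    return manifest_path
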
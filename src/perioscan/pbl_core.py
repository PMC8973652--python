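"""Per-tooth periodontal bone loss (PBL%) computation and periodontitis staging.

Radiographic staging of periodontitis rests on six anatomical landmarks per
tooth: the mesial and distal cementoenamel junction (CEJ, ``m1``/``d1``), the
deepest alveolar crest on each side (``m2``/``d2``) and the root apex
(``m3``/``d3``; for unirooted teeth the two apices coincide).  Bone loss on one
side is the crest's displacement from the CEJ expressed as a fraction of root
length, and the tooth-level PBL% is the larger of the mesial and distal
fractions::

    PBL% = max( |m1 - m2| / |m1 - m3| ,  |d1 - d2| / |d1 - d3| )

with ``|a - b|`` the Euclidean distance between annotated points.  The stage
follows fixed thresholds: PBL% < 15% is stage I, 15-33% stage II and > 33%
stage III/IV (stages III and IV are merged; radiographs alone cannot separate
them, and no bone loss is subsumed under stage I because the clinical 2-mm
rule cannot be measured on a panoramic film).

This module also defines the annotation JSON dialect used across the package
for ground truth and predictions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

#: Root lengths below this (pixels) are degenerate annotations.
ZERO_ROOT_EPS = 1e-6

#: Stage II begins at this PBL fraction (inclusive).
STAGE_II_LOWER = 0.15
#: Stage II ends at this PBL fraction (inclusive); above it is stage III/IV.
STAGE_II_UPPER = 0.33

KEYPOINT_NAMES = ("m1", "m2", "m3", "d1", "d2", "d3")


class PBLError(ValueError):
    """Base class for staging errors."""


class ZeroRootLength(PBLError):
    """CEJ and apex coincide: root length is below :data:`ZERO_ROOT_EPS`."""

    def __init__(self, side: str = "") -> None:
        self.side = side
        super().__init__(f"zero root length{' on ' + side if side else ''}")


class OutOfRange(PBLError):
    """A PBL fraction outside [0, 1] was passed to stage assignment."""


class Stage(str, Enum):
    """Periodontitis stage by bone-loss fraction; III and IV merged."""

    I = "I"
    II = "II"
    III_IV = "III_IV"

    @property
    def ordinal(self) -> int:
        """1-based ordinal code (I=1, II=2, III_IV=3), used by rater tables."""
        return {"I": 1, "II": 2, "III_IV": 3}[self.value]


STAGE_ORDER = (Stage.I, Stage.II, Stage.III_IV)


@dataclass(frozen=True)
class Point2D:
    """A pixel-space point: x is the column (rightward), y the row (downward)."""

    x: float
    y: float

    def distance_to(self, other: "Point2D") -> float:
        return math.hypot(self.x - other.x, self.y - other.y)

    def as_tuple(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass(frozen=True)
class KeypointSet:
    """The six landmarks of one tooth, in image coordinates.

    ``m*`` points sit on the mesial side (toward the arch midline), ``d*`` on
    the distal side.  ``unirooted`` teeth must have coincident apices
    (``m3 == d3``).
    """

    m1: Point2D
    m2: Point2D
    m3: Point2D
    d1: Point2D
    d2: Point2D
    d3: Point2D
    tooth_id: str = ""
    unirooted: bool = False

    def points(self) -> dict[str, Point2D]:
        return {name: getattr(self, name) for name in KEYPOINT_NAMES}


@dataclass(frozen=True)
class PBLResult:
    """Mesial and distal bone-loss fractions and the staging-relevant maximum."""

    pbl_mesial: float
    pbl_distal: float
    pbl_max: float
    side_used: str  # "mesial" or "distal"


@dataclass(frozen=True)
class StagedTooth:
    """A fully staged tooth: landmarks, PBL fractions, stage and lesion flags."""

    keypoints: KeypointSet
    pbl: PBLResult
    stage: Stage
    vertical_lesion: bool = False
    furcation_lesion: bool = False


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------

def compute_side_pbl(cej: Point2D, crest: Point2D, apex: Point2D) -> float:
    """Bone-loss fraction on one side: dist(cej, crest) / dist(cej, apex).

    The result is clamped to [0, 1]: a crest detected slightly beyond the apex
    (possible with noisy detections) saturates at total loss rather than
    erroring out.

    Raises
    ------
    ZeroRootLength
        If the CEJ-apex distance is below :data:`ZERO_ROOT_EPS` pixels.
    """
    root_len = cej.distance_to(apex)
    if root_len < ZERO_ROOT_EPS:
        raise ZeroRootLength()
    ratio = cej.distance_to(crest) / root_len
    return min(max(ratio, 0.0), 1.0)


def compute_pbl(kp: KeypointSet) -> PBLResult:
    """Both sides' bone-loss fractions; the larger one is the staging basis.

    Ties between sides report mesial (the stage is unaffected either way).
    """
    try:
        mesial = compute_side_pbl(kp.m1, kp.m2, kp.m3)
    except ZeroRootLength:
        raise ZeroRootLength("mesial") from None
    try:
        distal = compute_side_pbl(kp.d1, kp.d2, kp.d3)
    except ZeroRootLength:
        raise ZeroRootLength("distal") from None
    if mesial >= distal:
        return PBLResult(mesial, distal, mesial, "mesial")
    return PBLResult(mesial, distal, distal, "distal")


def assign_stage(pbl_max: float) -> Stage:
    """Map a bone-loss fraction to its stage: <15% I, 15-33% II, >33% III/IV.

    Both printed boundaries (15% and 33%) belong to stage II.
    """
    if not (0.0 <= pbl_max <= 1.0) or math.isnan(pbl_max):
        raise OutOfRange(f"PBL fraction {pbl_max!r} outside [0, 1]")
    if pbl_max < STAGE_II_LOWER:
        return Stage.I
    if pbl_max <= STAGE_II_UPPER:
        return Stage.II
    return Stage.III_IV


def stage_tooth(
    kp: KeypointSet, vertical: bool = False, furcation: bool = False
) -> StagedTooth:
    """Compute PBL from the landmarks, assign the stage, carry lesion flags."""
    pbl = compute_pbl(kp)
    return StagedTooth(
        keypoints=kp,
        pbl=pbl,
        stage=assign_stage(pbl.pbl_max),
        vertical_lesion=vertical,
        furcation_lesion=furcation,
    )


def validate_keypoints(kp: KeypointSet) -> list[str]:
    """Report annotation defects; an empty list means the set is clean.

    Issue codes:

    - ``ZeroRootLength:<side>`` — CEJ and apex coincide on that side;
    - ``ApexMismatch`` — a unirooted tooth whose two apices differ;
    - ``CrestOutsideRoot:<side>`` — crest farther from the CEJ than the apex
      (the unclamped fraction would exceed 1).

    The validator never raises.
    """
    issues: list[str] = []
    for side, (cej, crest, apex) in {
        "mesial": (kp.m1, kp.m2, kp.m3),
        "distal": (kp.d1, kp.d2, kp.d3),
    }.items():
        root_len = cej.distance_to(apex)
        if root_len < ZERO_ROOT_EPS:
            issues.append(f"ZeroRootLength:{side}")
        elif cej.distance_to(crest) > root_len * (1 + 1e-9):
            issues.append(f"CrestOutsideRoot:{side}")
    if kp.unirooted and kp.m3.distance_to(kp.d3) > ZERO_ROOT_EPS:
        issues.append("ApexMismatch")
    return issues


# ---------------------------------------------------------------------------
# Annotation JSON dialect
# ---------------------------------------------------------------------------
# One JSON document per image.  Per tooth: tooth_id, the six keypoints as
# {"x": float, "y": float} in 0-based pixel coordinates, the unirooted flag,
# the stage label, lesion boxes as half-open [x_min, y_min, x_max, y_max]
# pixel boxes with a class in {"vertical", "furcation"}, plus the side
# bookkeeping the simulator records: which crop side is mesial ("left" or
# "right") and the crown orientation ("up" or "down").

@dataclass
class ToothAnnotation:
    """One tooth's record in the annotation dialect."""

    tooth_id: str
    keypoints: KeypointSet
    stage: Stage
    unirooted: bool = False
    mesial_side: str = "left"  # which image side of the tooth faces the midline
    orientation: str = "up"  # crown direction: "up" (mandible) or "down" (maxilla)
    lesion_boxes: list[dict] = field(default_factory=list)

    @property
    def vertical_lesion(self) -> bool:
        return any(b["class"] == "vertical" for b in self.lesion_boxes)

    @property
    def furcation_lesion(self) -> bool:
        return any(b["class"] == "furcation" for b in self.lesion_boxes)


def tooth_to_dict(t: ToothAnnotation) -> dict:
    return {
        "tooth_id": t.tooth_id,
        "keypoints": {
            name: {"x": p.x, "y": p.y} for name, p in t.keypoints.points().items()
        },
        "unirooted": t.unirooted,
        "stage": t.stage.value,
        "mesial_side": t.mesial_side,
        "orientation": t.orientation,
        "lesion_boxes": [
            {"class": b["class"], "box": [float(v) for v in b["box"]]}
            for b in t.lesion_boxes
        ],
    }


def tooth_from_dict(d: Mapping) -> ToothAnnotation:
    pts = {
        name: Point2D(float(d["keypoints"][name]["x"]), float(d["keypoints"][name]["y"]))
        for name in KEYPOINT_NAMES
    }
    kp = KeypointSet(
        tooth_id=str(d["tooth_id"]), unirooted=bool(d["unirooted"]), **pts
    )
    return ToothAnnotation(
        tooth_id=str(d["tooth_id"]),
        keypoints=kp,
        stage=Stage(d["stage"]),
        unirooted=bool(d["unirooted"]),
        mesial_side=d.get("mesial_side", "left"),
        orientation=d.get("orientation", "up"),
        lesion_boxes=[
            {"class": b["class"], "box": list(b["box"])} for b in d.get("lesion_boxes", [])
        ],
    )


def save_annotations(
    path: str | Path, teeth: Iterable[ToothAnnotation], image_size: tuple[int, int]
) -> None:
    """Write one image's annotation document. ``image_size`` is (height, width)."""
    doc = {
        "image_size": [int(image_size[0]), int(image_size[1])],
        "teeth": [tooth_to_dict(t) for t in teeth],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_annotations(path: str | Path) -> tuple[list[ToothAnnotation], tuple[int, int]]:
    """Read an annotation document; returns (teeth, (height, width))."""
    doc = json.loads(Path(path).read_text())
    teeth = [tooth_from_dict(d) for d in doc["teeth"]]
    h, w = doc["image_size"]
    return teeth, (int(h), int(w))
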
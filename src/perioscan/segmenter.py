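"""Stage 1: tooth segmentation, instance extraction and fixed-margin cropping.

A small encoder-decoder network with symmetric skip connections at every
level predicts a per-pixel tooth probability map; skip connections merge deep
(contextual) with shallow (edge-level) features, which is what makes the
architecture work on small medical-image datasets.  The semantic map becomes
per-tooth instances by thresholding, 8-connected component labelling and a
minimum-area filter, and each instance is cut out of the panorama with a
fixed 20-pixel margin beyond its tight bounding box (clipped at the image
border), keeping the crop offset so crop coordinates map exactly back to
panorama coordinates.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from skimage import measure

from . import nn
from .pbl_core import Point2D


class BadConfig(ValueError):
    pass


class EmptyDataset(ValueError):
    pass


class NonFiniteLoss(RuntimeError):
    pass


@dataclass
class SegmenterConfig:
    """Architecture and training defaults for the tooth segmenter.

    ``depth`` down/upsampling levels with ``base_channels`` doubling per level
    (capped at 64); loss is soft-Dice + binary cross-entropy under Adam.
    """

    depth: int = 3
    base_channels: int = 6
    epochs: int = 25
    learning_rate: float = 5e-3
    batch_size: int = 4
    seed: int = 0
    threshold: float = 0.5
    min_area: int = 30
    margin: int = 20
    downscale: int = 2  # segment at 1/downscale resolution; boxes upscaled back

    def validate(self) -> None:
        if self.depth < 2:
            raise BadConfig("depth must be >= 2")
        for name in ("base_channels", "epochs", "batch_size"):
            if getattr(self, name) <= 0:
                raise BadConfig(f"{name} must be positive")
        if self.learning_rate < 0:
            raise BadConfig("learning rate must be non-negative")


@dataclass
class ToothInstance:
    """One connected component of the binarized probability map."""

    contour: list[tuple[float, float]]  # (x, y) vertices
    mask: np.ndarray  # full-canvas boolean
    bbox: tuple[int, int, int, int]  # half-open (x0, y0, x1, y1)
    area: int


@dataclass
class ToothCrop:
    """An image patch around one tooth, with its panorama offset.

    Any point ``(x, y)`` in crop coordinates corresponds to
    ``(x + offset.x, y + offset.y)`` in the panorama, exactly.
    """

    pixels: np.ndarray
    offset: Point2D
    source_instance: ToothInstance | None = None


class UNetSegmenter:
    """Encoder-decoder with skip connections; single-channel logit output."""

    def __init__(self, config: SegmenterConfig) -> None:
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        d, b = config.depth, config.base_channels
        self.channels = [min(b * 2**i, 64) for i in range(d + 1)]
        self.enc = []
        in_ch = 1
        for i in range(d):
            ch = self.channels[i]
            self.enc.append(
                nn.Sequential(nn.conv_block(rng, in_ch, ch), nn.conv_block(rng, ch, ch))
            )
            in_ch = ch
        self.pools = [nn.MaxPool2() for _ in range(d)]
        bott = self.channels[d]
        self.bottleneck = nn.Sequential(
            nn.conv_block(rng, in_ch, bott), nn.conv_block(rng, bott, bott)
        )
        self.ups = [nn.Upsample2() for _ in range(d)]
        self.dec = []
        below = bott
        for i in reversed(range(d)):
            ch = self.channels[i]
            self.dec.insert(
                0,
                nn.Sequential(
                    nn.conv_block(rng, ch + below, ch), nn.conv_block(rng, ch, ch)
                ),
            )
            below = ch
        self.head = nn.Conv2d(rng, self.channels[0], 1, k=1)

    @property
    def params(self) -> list[nn.Param]:
        ps: list[nn.Param] = []
        for block in (*self.enc, self.bottleneck, *self.dec):
            ps.extend(block.params)
        ps.extend(self.head.params)
        return ps

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Logits, same spatial size as the input (H, W divisible by 2^depth)."""
        d = self.config.depth
        skips = []
        h = x
        for i in range(d):
            h_enc = self.enc[i].forward(h, train=train)
            skips.append(h_enc)
            h = self.pools[i].forward(h_enc, train=train)
        h = self.bottleneck.forward(h, train=train)
        for i in reversed(range(d)):
            h = self.ups[i].forward(h, train=train)
            h = np.concatenate([skips[i], h], axis=1)
            h = self.dec[i].forward(h, train=train)
        return self.head.forward(h, train=train)

    def backward(self, grad: np.ndarray) -> None:
        d = self.config.depth
        grad = self.head.backward(grad)
        skip_grads: list[np.ndarray | None] = [None] * d
        for i in range(d):
            grad = self.dec[i].backward(grad)
            ch_skip = self.channels[i]
            skip_grads[i] = grad[:, :ch_skip]
            grad = self.ups[i].backward(grad[:, ch_skip:])
        grad = self.bottleneck.backward(grad)
        for i in reversed(range(d)):
            grad = self.pools[i].backward(grad)
            grad = grad + skip_grads[i]
            grad = self.enc[i].backward(grad)

    def predict_proba(self, image: np.ndarray) -> np.ndarray:
        """Tooth probability map for one uint8/float image, any size.

        The image is zero-padded on the right/bottom up to a multiple of
        2^depth and the padding removed from the output.
        """
        h, w = image.shape
        m = 2 ** self.config.depth
        ph, pw = (-h) % m, (-w) % m
        x = np.asarray(image, dtype=np.float32) / 255.0
        x = np.pad(x, ((0, ph), (0, pw)))[None, None]
        logits = self.forward(x, train=False)
        return nn.sigmoid(logits[0, 0, :h, :w])


def build_segmenter(config: SegmenterConfig | None = None) -> UNetSegmenter:
    return UNetSegmenter(config or SegmenterConfig())


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """2|A∩B| / (|A|+|B|) of two boolean masks; two empty masks score 1."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.logical_and(a, b).sum()) / denom


def _batch_loss(model: UNetSegmenter, x: np.ndarray, t: np.ndarray) -> float:
    """Dice + BCE on one batch; runs forward and backward."""
    logits = model.forward(x, train=True)
    n_el = logits.size
    bce, g_bce = nn.bce_with_logits(logits, t)
    p = nn.sigmoid(logits)
    eps = 1.0
    num = 2.0 * float((p * t).sum()) + eps
    den = float(p.sum() + t.sum()) + eps
    dice_loss = 1.0 - num / den
    dnum_dp = 2.0 * t
    g_dice = -(dnum_dp * den - num) / den**2 * p * (1 - p)
    loss = bce / n_el + dice_loss
    model.backward((g_bce / n_el + g_dice).astype(np.float32))
    return loss


def train_segmenter(
    model: UNetSegmenter,
    dataset: Sequence[tuple[np.ndarray, np.ndarray]],
    config: SegmenterConfig | None = None,
) -> tuple[UNetSegmenter, list[float]]:
    """Fit on (image, union-of-tooth-masks) pairs; returns the loss history.

    Images must share a shape divisible by 2^depth.  Raises
    :class:`EmptyDataset` on an empty dataset and :class:`NonFiniteLoss` with
    the offending epoch if the loss leaves the finite range.
    """
    cfg = config or model.config
    cfg.validate()
    if len(dataset) == 0:
        raise EmptyDataset("no training pairs")
    x = np.stack([np.asarray(im, dtype=np.float32) / 255.0 for im, _ in dataset])[:, None]
    t = np.stack([np.asarray(mk, dtype=np.float32) for _, mk in dataset])[:, None]
    m = 2**cfg.depth
    if x.shape[2] % m or x.shape[3] % m:
        raise BadConfig(f"image size {x.shape[2:]}, must be divisible by {m}")
    rng = np.random.default_rng(cfg.seed + 1)
    opt = nn.Adam(model.params, lr=cfg.learning_rate)
    history: list[float] = []
    n = len(dataset)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            opt.zero_grad()
            loss = _batch_loss(model, x[idx], t[idx])
            if not np.isfinite(loss):
                raise NonFiniteLoss(f"loss {loss} at epoch {epoch}")
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return model, history


# ---------------------------------------------------------------------------
# Instances and crops
# ---------------------------------------------------------------------------

def extract_instances(
    prob_map: np.ndarray, threshold: float = 0.5, min_area: int = 30
) -> list[ToothInstance]:
    """Threshold, 8-connected components, area filter; sorted by bbox x-center."""
    binary = np.asarray(prob_map) >= threshold
    labels = measure.label(binary, connectivity=2)
    instances: list[ToothInstance] = []
    for region in measure.regionprops(labels):
        if region.area < min_area:
            continue
        mask = labels == region.label
        r0, c0, r1, c1 = region.bbox
        contours = measure.find_contours(mask.astype(np.float32), 0.5)
        contour = max(contours, key=len) if contours else np.empty((0, 2))
        instances.append(
            ToothInstance(
                contour=[(float(c), float(r)) for r, c in contour],
                mask=mask,
                bbox=(int(c0), int(r0), int(c1), int(r1)),
                area=int(region.area),
            )
        )
    instances.sort(key=lambda t: (t.bbox[0] + t.bbox[2]) / 2)
    return instances


def crop_tooth(image: np.ndarray, instance: ToothInstance, margin: int = 20) -> ToothCrop:
    """Cut the instance's bbox expanded by ``margin`` px on all sides.

    The expansion is clipped at the image border; the recorded offset is the
    crop's top-left corner in panorama coordinates.
    """
    h, w = image.shape[:2]
    x0, y0, x1, y1 = instance.bbox
    cx0, cy0 = max(0, x0 - margin), max(0, y0 - margin)
    cx1, cy1 = min(w, x1 + margin), min(h, y1 + margin)
    return ToothCrop(
        pixels=image[cy0:cy1, cx0:cx1],
        offset=Point2D(float(cx0), float(cy0)),
        source_instance=instance,
    )


def upscale_instance(instance: ToothInstance, factor: int, shape: tuple[int, int]) -> ToothInstance:
    """Map an instance found at reduced resolution back to full resolution."""
    if factor == 1:
        return instance
    x0, y0, x1, y1 = instance.bbox
    h, w = shape
    mask = instance.mask.repeat(factor, axis=0).repeat(factor, axis=1)[:h, :w]
    if mask.shape != (h, w):
        mask = np.pad(mask, ((0, h - mask.shape[0]), (0, w - mask.shape[1])))
    return ToothInstance(
        contour=[(x * factor, y * factor) for x, y in instance.contour],
        mask=mask,
        bbox=(x0 * factor, y0 * factor, min(x1 * factor, w), min(y1 * factor, h)),
        area=int(mask.sum()),
    )


def segment_and_crop(
    model: UNetSegmenter, image: np.ndarray, params: SegmenterConfig | None = None
) -> list[ToothCrop]:
    """Predict the tooth map, extract instances and cut one crop per tooth.

    Segmentation runs at 1/``downscale`` resolution (tooth blobs need no
    fine detail); instance boxes and masks are mapped back to full
    resolution before the margin crop, which always uses the original image.
    """
    cfg = params or model.config
    s = max(1, cfg.downscale)
    prob = model.predict_proba(image[::s, ::s])
    instances = extract_instances(prob, cfg.threshold, max(1, cfg.min_area // (s * s)))
    instances = [upscale_instance(i, s, image.shape[:2]) for i in instances]
    return [crop_tooth(image, inst, cfg.margin) for inst in instances]


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: UNetSegmenter, directory: str | Path) -> Path:
    """Write weights (npz) plus the serialized config into a directory."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    (d / "config.json").write_text(json.dumps(asdict(model.config), indent=1))
    np.savez(d / "weights.npz", **{f"p{i}": p.value for i, p in enumerate(model.params)})
    return d


def load_checkpoint(directory: str | Path) -> UNetSegmenter:
    d = Path(directory)
    cfg = SegmenterConfig(**json.loads((d / "config.json").read_text()))
    model = UNetSegmenter(cfg)
    with np.load(d / "weights.npz") as data:
        for i, p in enumerate(model.params):
            p.value[...] = data[f"p{i}"]
    return model
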
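# Methods

## The staging computation

A tooth's radiographic bone loss is measured per side from three collinear
(or nearly collinear) landmarks: the cementoenamel junction (CEJ), the
deepest alveolar crest, and the root apex. The side's loss fraction is

    pbl_side = dist(CEJ, crest) / dist(CEJ, apex)

with `dist` the Euclidean distance between annotated points, and the tooth's
PBL% is the larger of the mesial and distal fractions. Stages: `< 0.15` → I,
`0.15–0.33` (both boundaries inclusive) → II, `> 0.33` → III/IV. Stage III
and IV are merged — separating them needs clinical complexity factors that a
radiograph alone does not carry — and "no bone loss" is folded into stage I
because the clinical 2-mm rule cannot be measured reliably at panoramic
scale.

Numerical choices: the ratio is clamped to [0, 1] (a crest detected slightly
beyond the apex reads as total loss rather than an error, so noisy
detections still stage); root lengths below 1e-6 px raise `ZeroRootLength`;
ties between sides report the mesial side (the stage is unaffected). An
open question in the measurement definition is whether clinicians measure
along the tooth's long axis rather than point-to-point; the two coincide
when the three points are collinear, which the simulator guarantees by
construction, so the package adopts the simpler point-to-point reading.

## Synthetic scenes

`panorasim` renders a parametric dental arch on a 512×256 8-bit canvas (two
rows of teeth; crown polygon + one- or two-rooted root polygon over a darker
jaw band). The controlled quantity is the crest position along each
CEJ→apex segment: per-side bone fractions are drawn uniformly from the
target stage's interval (I: [0, 0.15), II: [0.15, 0.33], III/IV:
(0.33, 0.9]), so the stage label follows analytically. Keypoints, masks,
stage and lesion boxes are computed from the generating parameters, never
recovered from pixels, and `verify_ground_truth` re-checks every invariant
(including stage recomputation through `pbl_core`).

A vertical (angular) defect deepens one side's crest locally; its extra
drop is sampled jointly with the base bone level so the *effective* crest
fraction stays inside the target stage's interval. This keeps the requested
stage mix exact, which the generator treats as a contract (the defect is
then a shape/appearance perturbation, not a stage perturbation). Furcation
radiolucencies are dark blobs between the roots of two-rooted teeth.
Mesial/distal is defined as toward/away from the arch midline and recorded
per tooth. Rendering adds Gaussian blur (σ = 0.8) and additive Gaussian
noise (sd = 5); the "easy" regime sets both to zero. Default rates:
vertical defects on 15% of teeth, furcation lesions on 25% of two-rooted
teeth; stage mix 0.5 / 0.3 / 0.2.

Reproducibility: image *i* of a dataset uses the generator spawned from
`SeedSequence(root_seed, spawn_key=(i,))`, so any subset regenerates
identically.

What the simulator does **not** emulate: projection geometry, ghost images,
spine shadow, overlapping or misplaced teeth, soft-tissue texture. Passing
tests therefore demonstrate that the pipeline's geometry, bookkeeping and
learning machinery work — not clinical accuracy on real radiographs.

## Networks

Both networks run on a small numpy CNN engine (`nn.py`): im2col
convolutions with hand-derived backward passes, leaky-ReLU, 2× max pooling,
stride-1 "same" max pooling, nearest-neighbour upsampling and Adam
(gradient clip ±10). Finite-difference tests pin every layer's gradients.
Initialisation is He-scaled from an explicit seeded generator, so models are
bit-reproducible from `(config, seed)`.

**Segmenter** — encoder–decoder with symmetric skip connections at each of
`depth = 3` levels (channels 6/12/24, bottleneck 48), Dice + BCE loss,
Adam lr 5e-3, batch 4, 25 epochs. The segmenter works on a 2× downscaled
panorama: tooth blobs carry no detail that survives at full resolution,
and halving the grid quarters compute; instance boxes and masks are
upscaled exactly afterwards, and the margin crop always uses the original
image. Instances = threshold 0.5 → 8-connected components → area ≥ 30 px²
(full-resolution equivalent) → sort by x-centre. Touching-teeth splitting
(watershed etc.) is out of scope; synthetic teeth are separated.

**Detector** — a deliberately tiny YOLO-family model (~46k parameters):
stem + three stride-2 CSP blocks (channels 8/16/24/32), SPP (identity +
3×3 + 5×5 stride-1 max pools, fused 1×1), PAN-style top-down + bottom-up
fusion, and 1×1 heads at strides 8 and 16 with 2 anchors each. Crops are
resized to 128×80 for the forward pass and detections mapped back. Losses:
CIoU for boxes (gradient by central differences through the decode map —
a handful of matched anchors per image makes this cheap and robust),
BCE for objectness (positive weight 4) and classes; Adam lr 3e-3, batch 8,
90 epochs. Anchor priors default to two small squares (keypoints) and two
larger rectangles (lesions); `compute_anchors` re-estimates them by
IoU-distance k-means with deterministic area-quantile initialisation.

**Keypoints as boxes.** Each landmark becomes a 12-px square box centred on
the point with one of three appearance classes (cej, crest, apex). Whether
a point is mesial or distal is spatial, not visual, so it is resolved after
detection: CEJ and crest candidates are split at the crop's vertical
midline (best score per side wins), apex pairs are ordered by x, and a
single apex detection serves both sides — exactly the unirooted case. If
one side misses a role, the complete side's whole CEJ–crest–apex triple is
mirrored onto it, so the stage rests on the measurable side; naively
pairing a lone crest with the opposite side's CEJ would fabricate large
bone loss. Only roles absent on both sides make a tooth "incomplete";
incomplete teeth are reported, never staged, and never abort a scene.

## Pipeline conventions

- All boxes are half-open `[x0, x1) × [y0, y1)`, 0-based; points are pixel
  centres. Under a horizontal flip points map `x → W−1−x` and box edges
  `[x0, x1) → [W−x1, W−x0)`.
- The 80/20 split (`floor(n·0.8)` training items by seeded shuffle) happens
  before augmentation; only training images are augmented.
- Augmentation is the flip family {identity, hflip, vflip, rot180} — the
  unique involution set of size 4 closed under composition — giving exactly
  4× the training count. A horizontal flip swaps the recorded mesial side,
  a vertical flip the jaw orientation; stages are invariant.
- The crop rule expands each instance's tight box by 20 px on every side,
  clipped at image borders, with the offset kept so crop + offset =
  panorama coordinates exactly.

## Evaluation suite

Staging is scored with a 3-class confusion matrix (rows = reference) and
one-vs-rest accuracy/precision/sensitivity/specificity/F1; "overall" values
are unweighted macro means over the three stages (micro pooling is a
flag), and overall accuracy is trace/total. Zero-denominator rates are
returned as flagged `None`, never NaN. Detection uses greedy
highest-score-first IoU matching (threshold 0.5, each truth matchable
once) and all-points interpolated average precision. ROC curves sweep the
distinct scores; AUC (trapezoid) equals the normalised Mann–Whitney U.
Rater agreement is ICC(2,1) — two-way random effects, absolute agreement,
single rater — via the standard mean-squares decomposition (an
all-constant table is defined as 1 and flagged degenerate); group
comparisons use Pearson's chi-square without continuity correction.

## Default problem sizes and measured recovery

The documented desk-scale runs (also the test-suite defaults) use 40 clean
scenes at 512×256 with 12 teeth each, split 32/8, seed 7:

- segmenter: held-out mean per-tooth mask IoU 0.92 (threshold 0.7),
- detector: held-out mean keypoint centre error ≈ 1.3 px (threshold 5 px),
- end-to-end staging accuracy 0.948 over 96 held-out teeth (threshold
  0.9); residual errors sit within a few percent of the 15%/33% stage
  boundaries, where a ~1–2 px crest error on a ~60 px root is decisive.

## Known limitations

- No batch/group normalisation; training relies on small learning rates and
  gradient clipping, adequate at this model scale.
- The instance rule cannot split touching teeth.
- Lesion detection is trained but only its plumbing is asserted; synthetic
  lesion appearance is too stylised to claim detection quality.
- Real-radiograph ingestion (DICOM, machine calibration) is out of scope.
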
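# Methods

`germquant` quantifies parasitic-seed germination bioassays from disk
images. A germination assay spreads 50–100 preconditioned seeds of a root
parasite (*Striga*, *Orobanche*, *Phelipanche*) on a glass-fiber disk,
exposes them to a germination stimulant, and scores the fraction of seeds
whose radicle — the embryonic root, visible as a thin white-transparent
protrusion through the dark seed coat — has emerged. The package replaces
manual counting with an object-detection pipeline and provides a synthetic
image generator so that every stage is testable end to end.

## The disk simulator

No public image set accompanies this task, so the simulator is a
first-class component, not a fixture. It emulates the assay's imaging
conditions:

- a bright circular glass-fiber disk (radius 0.47 × image side) on a
  neutral background, with spatially uncorrelated fiber texture;
- `n_seeds` dark brown ovoid seeds (default drawn uniformly in [50, 100]
  per disk), rendered as rotated ellipses with semi-major axis drawn from
  `seed_axis_range` (default 9–15 px at the default 512×512 canvas) and
  semi-minor axis 0.55–0.80 of it;
- each seed germinates independently with probability
  `germination_fraction` (default 0.55, the long-run per-disk average in
  this kind of assay); `exact_counts=True` instead forces exactly
  `round(n·p)` germinated seeds for deterministic tests;
- a germinated seed carries a radicle: a cubic-Bézier stroke of width
  2–4 px leaving one pole of the ellipse, with length drawn from
  `radicle_length_range` (default 14–42 px — radicle development is
  uneven and lengths vary widely). Radicles are alpha-blended toward
  white with weight `radicle_contrast`; 0 renders them invisible, and low
  values emulate the poor contrast of fresh radicles against white filter
  paper. Radicles may freely cross seeds and other radicles — the tangle
  of radicles over seed coats is the hard case the detector must face;
- optional confusers reproduce documented failure modes of real assays:
  gray debris blobs (unlabeled distractors) and, on non-germinated seeds,
  a small white protuberance of the seed coat that mimics a short radicle
  (`protuberance_probability`).

Seed centers are rejection-sampled inside the disk under a minimum
pairwise distance that interpolates from 1.9 × mean semi-major axis at
`overlap_intensity = 0` down to 4 px at 1; infeasible packings fail with
an explicit error after a bounded number of attempts.

Every ground-truth box is computed as the tight axis-aligned box of the
object's own rasterized pixel mask, so tightness (IoU 1.0 against a
recomputed mask) holds by construction, and the simulator knows which
radicle belongs to which seed — richer information than either annotation
scheme retains. The two schemes project from it: `S_R` boxes every seed
coat (`S`) and every radicle (`R`) separately; `NGS_GS` boxes
non-germinated seeds (`NGS`) and the union of seed + radicle for
germinated ones (`GS`).

What the simulator does **not** model: photorealistic optics (defocus,
vignetting, specularities), seed-coat texture variation between species,
grayscale capture, or annotation noise. Passing tests therefore
demonstrate that the pipeline's machinery is correct and that the
detector can learn the geometry of this task at desk scale — not that
any particular accuracy carries over to real micrographs.

## The detector

A two-stage, anchor-based design. A frozen feature extractor maps the RGB
image to a stride-4 feature volume; a region-proposal stage scores and
regresses 9 anchors (3 scales × 3 aspect ratios) at every feature
location; an ROI head classifies pooled proposal features into the
scheme's classes plus background and refines the box.

**Backbone.** The default extractor is a fixed multi-scale filter bank
(8 channels: block mean/min/max intensity, mean and max thin-bright-ridge
response — the positive residual over a Gaussian background — mean and
max Sobel gradient magnitude, and local standard deviation). Freezing it
keeps CPU training to the proposal and head parameters and makes feature
maps cacheable per image. The backbone is a pluggable contract (stride +
channel count + callable); names of heavy residual networks are reserved
in the registry but intentionally not shipped.

**Anchors.** Stride 4, scales {14, 22, 34} px, ratios {0.5, 1, 2}.
These were chosen by measuring anchor-to-ground-truth IoU coverage on
simulated disks: seed boxes run ~13–27 px and radicle boxes ~5–40 px, and
a coarser stride-8 grid caps the best achievable anchor IoU near 0.5–0.6,
below the 0.7 positive-assignment threshold, which starves the proposal
stage of positive examples. All values are config-exposed.

**Assignment.** An anchor is positive when its best IoU over ground-truth
boxes exceeds 0.7 (matched to the argmax box), negative below 0.3, and
ignored in between — excluded from both loss terms. Additionally every
ground-truth box force-claims its best-IoU anchor even below threshold;
without this rule small radicle boxes can have no positive anchor at all
and become untrainable. The head reuses the same assignment rule on
proposals with thresholds 0.5/0.5 (no ignore band); 0.7/0.3 on proposals
would leave the head almost no foreground samples.

**Losses and optimization.** Proposal objectness and head classification
use softmax cross-entropy (the head carries an explicit background
class); box regression uses smooth L1 (quadratic below 1) on
(tx, ty, tw, th) deltas — center offsets normalized by anchor size, log
size ratios — applied only to positive anchors/foreground proposals.
Training follows the standard recipe: Adam, learning rate 0.01, batches
of two images, flip augmentation presenting each image also mirrored
about the vertical and horizontal axes with boxes transformed
consistently, and best-on-validation model selection (lowest validation
mAE) to avoid overfitting. Per image, up to 256 anchors (≤50% positive)
and up to 128 proposals (≤25% foreground) enter the losses. Positive
samples are stratified per matched object — weights inverse to the
number of positive anchors an object owns — so a radicle with a single
force-matched anchor is trained as often as a seed with dozens. A
hard-negative-mining option exists (`hard_negative_fraction`) but
defaults to off: mining suppresses near-radicle anchors (the hardest
negatives under the 0.3 threshold) and measurably destroys radicle
proposal recall. All gradients are computed by hand-written backward
passes (im2col convolutions, linear layers, ReLU) against numpy; the
optimizer state, sampling and initialization are fully seeded, so two
runs with the same seed produce identical loss sequences.

**Thin objects and proposal budgets.** Radicles stress anchor-based
detection in a specific way: at any finite anchor granularity, an anchor
one stride off a 2–4 px-wide stroke falls below IoU 0.3 against it and is
labeled background despite nearly identical appearance. Objectness for
radicle anchors therefore saturates mid-range instead of approaching 1,
and they rank below thousands of easy seed anchors. Two deliberate
responses: (1) inference uses larger proposal budgets than training
(top 20,000 scored anchors, 1,500 proposals after NMS, vs 6,000/600
during training) so radicle anchors survive into the head, which
discriminates them well; (2) the final per-class NMS threshold defaults
to 0.2 rather than the conventional 0.5, because shifted duplicates of a
thin diagonal box have pairwise IoU far below 0.5 and otherwise inflate
radicle counts severalfold. Both values, and the 0.5 confidence cutoff
used for counting, were selected on the validation split only.

## Census

Detections become counts per class and a germination rate per disk.
Under `S_R` the rate is `min(1, R/S)` — every germinated seed retains a
visible coat, so `S` counts all seeds and `R` the germinated ones —
undefined (flagged, not thrown) when no seed is detected. Under `NGS_GS`
it is `GS/(GS+NGS)`. `NGS` detections nested inside `GS` boxes are *not*
suppressed: that double-count risk is inherent to the NGS/GS labelling
scheme and is reported rather than silently corrected. The batch census
writes one CSV row per image (counts, rate as a percentage with two
decimals, empty when undefined) and converts per-image failures into
error rows instead of aborting.

## Evaluation

Two deliberately different axes:

- **Detection (AP/mAP).** Predictions of one class, pooled over the test
  set and ranked by confidence, are matched greedily one-to-one to
  ground truth at an IoU threshold (default 0.5, config-exposed): a
  prediction is a true positive when its best-IoU unmatched ground-truth
  box in its own image exceeds the threshold. Sweeping the confidence
  cutoff yields precision–recall points; AP is the all-points
  interpolated area (right-continuous precision envelope integrated over
  recall), and mAP the unweighted class mean.
- **Counting (AE/mAE).** Per class, `AE = |y − t| / y` with `y` the
  ground-truth and `t` the predicted count; mAE is the class mean. By
  default AE is computed per image and averaged over images, then
  classes; a pooled-counts alternative is available. Conventions at the
  formula's singularity: a class absent from both sides contributes
  nothing (and scores AP 1.0 — correct silence); spurious detections
  against zero ground truth contribute the absolute miscount.

The two axes rank detectors differently by design — a tight localizer
that misses objects beats a loose counter on mAP and loses on mAE — and
the test suite contains a constructed pair demonstrating exactly that.
Evaluation refuses to run on the training split.

## Scaled-down experiment sizes

The end-to-end experiment used by the acceptance script trains on 40
simulated disks (512×512, no crowding, radicle contrast 0.8), selects on
8 validation disks and evaluates blind on 10, for 1,000 Adam iterations
with validation every 100 — sizes chosen so the frozen-backbone detector
trains to its plateau in minutes on a single CPU while exercising every
pipeline stage. The window matters: seed detection converges within a
few hundred iterations, but radicle detection can emerge late (sometimes
only after ~900 iterations, depending on initialization), and the
optimization oscillates at this learning rate, so best-on-validation
selection over a sufficiently long run is what makes the result reliable.
The full-scale defaults (5,000 iterations; 2,000 for fine-tuning) remain
the configuration defaults.

## Known limitations

- The frozen filter-bank backbone cannot adapt features to new imaging
  conditions; radicle detection quality is proposal-limited, and radicle
  AP is far below seed AP even when counting error is acceptable.
- Aggressive per-class NMS (0.2) can merge genuinely overlapping
  radicles in heavily crowded disks.
- The simulator's germination rate is recoverable exactly from its own
  ground truth; real-image accuracy claims are outside what these tests
  can establish.
- Single-scale feature map only; no feature-pyramid multi-scale heads.
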
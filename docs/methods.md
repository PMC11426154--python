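# Methods

## Problem and pipeline

Lymphovascular invasion (LVI) — tumor cells inside the lumen or wall of a
blood or lymphatic vessel — is rare per slide (often a handful of vessels
among thousands) and small relative to a gigapixel scan. The pipeline
therefore splits the problem in two: first find every vessel (a
segmentation problem with extreme class imbalance but abundant positives),
then judge each found vessel for invasion (a classification problem with
few positives but a tightly cropped field of view). Epithelial
displacement is pooled with true invasion into one positive class to
favor sensitivity; the three-way annotation (clean / luminal invasion /
intramural invasion) is preserved in the ground-truth metadata.

## Synthetic slides

The generator produces the study conditions every stage is trained and
evaluated under. A scene is a H&E-palette plane with an alveolar-like
background (pale airspace, thin septa from thresholded smooth noise, mild
Gaussian pixel noise) on which vessels are placed uniformly at random.

* **Calibers.** Diameters are drawn uniformly from each class's
  physical range: arteries 100–500 μm, veins 100–200 μm, capillaries
  10–50 μm, lymphatics 20–30 μm, converted to pixels through the plane's
  microns-per-pixel (mpp). Wall thickness is class-specific (arteries
  muscular ~35% of the radius, lymphatics endothelium-thin ~15%).
* **Geometry.** A vessel is a rotated ellipse (eccentricity ≤ 0.8):
  an eosin-pink wall ring around a pale lumen. The annotated polygon is
  the outer ellipse (wall plus lumen — all tunicae), and the truth mask
  is by construction exactly the union of the rasterized polygons.
* **States.** Luminal invasion renders a hematoxylin-dark embolus that is
  a shrunk copy of the lumen ellipse (shape matched to the lumen,
  strictly inside it, disjoint from the wall). Intramural invasion
  scatters dark nests inside the wall ring only. Clean vessels contain no
  tumor pixel, so label soundness is assertable on the rendered masks.
* **Hygiene rules.** Placement enforces a ≥2-px gap between vessel masks
  and a 2-px clearance from the plane border; polygons never overlap.
  A vessel that cannot be placed within the retry budget (default 200
  positions) raises an explicit error naming the caliber class.
* **Stain drift.** `stain_jitter` applies a global LAB-space shift/scale
  to the rendered plane, emulating inter-laboratory staining variation
  for the normalizer to correct.

What the generator deliberately does **not** emulate: nuclear texture,
bronchiolar/epithelial distractors, multi-lumen twisted vessels, scanner
pyramids, tissue folds. Passing tests on these scenes demonstrates that
the pipeline's machinery (losses, tiling, normalization, training,
instance logic, metrics) is correct and learnable at desk scale — not
that the models would reach clinical performance on real tissue.

## Stage 1: segmentation

The loss is `α·WCE + β·Dice_FG + γ·Dice_BG` with (α, β, γ) = (0.5, 0.2,
0.3). WCE class weights default to inverse class frequency computed per
batch, rescaled to mean 1; Dice smoothing is ε = 1.0 in numerator and
denominator; probabilities are clipped at 1e-7 before logs. The gradient
of the full loss w.r.t. the probability map is analytic (the Dice terms
have a closed-form quotient derivative) and is verified against finite
differences in the tests.

Network inputs are standardized to [-1, 1]. This is not cosmetic: H&E
tiles are mostly pale (unit-range mean near 0.9), and uncentered inputs
bias every ReLU path — on the synthetic scenes centering roughly halves
the epochs needed to a given validation IoU.

The model is a fully convolutional encoder–decoder: conv→pool→conv, an
optional atrous context block (parallel 3×3 convolutions at dilations
1/2/4, summed — a lightweight spatial-pyramid), nearest upsampling, a
skip concatenation from the encoder, a refinement convolution and a 1×1
head. Width is set by `base_channels` (default 8 — "tiny"); the same
class scales up by widening. All layers are implemented in numpy (NCHW,
float32) with hand-written backward passes and He-normal seeded
initialization; the optimizer is Adam. Seeded end to end, training is
bit-reproducible.

Training defaults follow the study protocol (lr 1e-4, batch 16, 0.3×
decay at epoch 12, ≤250 epochs, early stopping on validation IoU with
patience 20). The desk-scale pipeline overrides the schedule (see
"Problem sizes" below) because the tiny model on synthetic tiles
converges in tens of epochs at a larger learning rate.

Inference tiles the plane on a regular grid (default 50% overlap),
optionally reflection-pads each tile (2×, original in the top-left block;
numpy "reflect" convention — no duplicated boundary row; "symmetric"
available), optionally averages the 8 dihedral test-time views (exactly
invertible, so TTA adds no interpolation error), mean-stitches
overlapping tiles and thresholds at 0.5. The desk-scale pipeline applies
a 1-px-radius binary closing to the mask before instance extraction; the
radius must stay below half the generator's minimum inter-vessel gap or
adjacent instances merge.

## Stage 2: classification

8-connected components of the binary mask become vessel instances;
components smaller than a 10-μm disk (the smallest printed caliber) are
dropped. Each instance's bounding box is tiled by a 128-μm grid anchored
at the box origin; a cell is kept when it holds ≥5% **of the instance's
mask pixels** (measuring against the instance, not the cell, keeps the
single tile of a small capillary and drops marginal slivers of large
vessels). Kept cells are cropped from the plane (translated inward at
plane edges), pixels outside the instance's own mask are whited out —
the classifier judges this vessel only, so a neighboring vessel's embolus
in the same crop cannot flip the verdict — and the crop is resized
bilinearly to 224×224.

The ensemble has three members of differing width, depth, pooling and
input scale (32/32/64 px): heterogeneity at desk scale stands in for
distinct large CNN families. Two members use global max pooling
("is the feature present anywhere" — the right bias for small emboli),
one global average pooling. Members train independently with Adam on
weighted cross-entropy (inverse-frequency class weights, mean-1
rescaled), keeping the best-validation checkpoint; the ensemble
probability is the unweighted mean. A vessel is invasive iff any tile's
ensemble probability reaches the threshold (0.5) — the any-tile rule
maximizes sensitivity, which is the clinical priority.

## Evaluation

Segmentation: IoU, FBeta (β = 1), recall from the binary mask; AUC-ROC as
a rank statistic over the probability plane (subsampled to ≤1e6 pixels,
seeded). Classification: F1, precision, sensitivity, specificity at the
threshold plus threshold-free AUC-ROC. Single-class truth yields NaN AUC
with a warning. Vessel-level evaluation is lesion-style: each **truth**
vessel is scored by the maximum invasive probability over predicted
instances overlapping its polygon (0 when missed), so fragmentation of
the predicted mask cannot double-count vessels. All metric paths are
tested against exhaustive confusion-matrix and Mann-Whitney oracles.

An oracle-classifier mode (tile probability 1 iff the tile contains a
planted tumor pixel lying on the instance's own pixels) validates the
instance/tile plumbing end to end: with truth-mask instances it recovers
the planted invasive count exactly.

## Problem sizes and numerical choices

The default desk-scale pipeline uses 288²-px planes at 2.0 μm/px (so a
200-μm vein is ~100 px and the 128-μm classifier tile is 64 px), 8
training + 3 validation + 5 test slides of 7 vessels each (veins,
capillaries, lymphatics; arteries excluded from the default vocabulary
because a 500-μm artery would not fit the small planes), segmentation on
64-px bbox crops with dihedral augmentation (learning rate 5e-3, 35
epochs, 0.3× decay at epoch 26 — with standardized inputs the tiny model
converges far faster than the full-scale protocol would suggest), and
classifier tiles augmented the same way (20 member epochs). Stain normalization uses random targets on
training planes and the deterministic template mean at inference.
Training runs minutes on one CPU; all randomness flows from one pipeline
seed through named substreams (scenes, stain targets, shuffling, init),
below 2³¹.

Other defaults: μm→px conversion rounds half-up with a 1-px floor; pixel
rectangles are half-open, 0-based; the fixed tiling grid treats the
printed 2040×2048 cell as 2048²; dataset splitting uses floor quotas with
leftovers assigned by a priority list (the only rule consistent with both
published split tuples); bbox tiles clamp by translation, never scaling.

## Known limitations

* The numpy engine is single-threaded and desk-scale; it is not a path
  to full-resolution WSIs, and the published large-backbone scores are
  out of reach by design.
* Flat-shaded sprites make segmentation easier than real tissue;
  reported IoU/AUC quantify the pipeline, not clinical accuracy.
* Intramural invasion in the thinnest lymphatics (20–30 μm at 2 μm/px)
  spans only a few pixels; its detectability at this working resolution
  is marginal, which bounds vessel-level sensitivity on synthetic scenes.
* Blood-vs-lymphatic discrimination at inference is out of scope; the
  segmenter treats all vessels as one foreground class.
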
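# Methods

## Problem and pipeline

Duplex chromogenic RNA in situ hybridization (RISH) renders individual
transcripts of two targets as small colored dots — here blue
(HRP/wild-type *HMGA2*) and red (AP/truncated *HMGA2*) — on a pale
counterstained tissue background. Quantification reduces to a
per-chromogen binary segmentation of dots, connected-component
counting per 40× field, and either a per-sample mean count or an
ordinal rubric score. The pipeline stages are:

1. **Preprocessing.** Global min–max normalization of each field to
   [0, 1]; CLAHE applied independently to each RGB channel (clip limit
   2.0 in 8-bit histogram units, contextual tiles of 8 × 8 px, 256
   bins); Gaussian blur with a 3 × 3 kernel, σ = 1.0. The stage order
   (normalize → CLAHE → Gaussian) follows the narrative order of the
   standard protocol; min–max is global per image rather than
   per channel (a config switch offers per-channel). CLAHE operates on
   an 8-bit quantization of each channel because its histogram bins are
   integer-valued; the scikit-image backend takes tile size directly in
   pixels and a clip limit normalized by the bin count (2.0/256).
2. **Patching.** Non-overlapping 64 × 64 tiles, row-major; images whose
   sides are not multiples of 64 are reflect-padded and the padding is
   cropped away after stitching, making
   `stitch(extract(x)) == x` bit-exact. Patch extraction applies
   identically to images and masks.
3. **Segmentation.** One binary Double U-Net per chromogen (see below),
   trained on patch/mask pairs with dice loss
   `1 − (2Σpg + ε)/(Σp + Σg + ε)`, ε = 1, Adam with learning rate
   0.001, on a seeded random 80/20 train/test split.
4. **Post-processing.** Threshold the stitched sigmoid map at 0.5;
   morphological opening (erode then dilate, 3 × 3 square, 1
   iteration) as the default despeckle — the operator sequence, element
   and iterations are configurable; count connected components at
   8-connectivity with area ≥ 2 px. Per-sample quantity = arithmetic
   mean of per-field counts (reported to 2 decimals).
5. **Scoring.** Per-field ordinal score from the dot count; blue bins
   0 | (0,20] | (20,40] | (40,60] | (60,80] | >80 and red bins
   0 | (0,10] | (10,20] | (20,30] | (30,40] | >40. The printed ranges
   overlap at every boundary, so bins are half-open with the shared
   edge assigned to the lower score (20 blue → 1, 21 → 2). A zero
   count scores 0 per channel. Sample score = sum over (nominally ten)
   fields; the positive-control convention of 4 per field sets the
   reference ceiling at 40, so raw sums above 40 (arithmetically
   possible, max 50) are flagged, never clamped. Positivity keeps
   samples with wild-type ≥ 4 OR truncated ≥ 3. Group summaries report
   n, mean and sample SD (ddof = 1; singleton groups report SD 0 with a
   degeneracy flag). Significance testing is deliberately out of scope.

## The Double U-Net

Each U-Net has 3 encoder levels of two (3 × 3 conv → batch norm → ReLU)
blocks followed by 2 × 2 max-pooling, a double-conv bottleneck, and a
mirrored decoder using 2 × 2 stride-2 transposed convolutions with skip
concatenation; a 1 × 1 convolution plus sigmoid emits per-pixel
foreground probability. Base width is 16 filters (doubling per level:
16/32/64, bottleneck 128), chosen so a 64 × 64 patch pools to 8 × 8 and
desk-scale CPU training stays feasible. The two U-Nets are stacked:
U-Net 1 sees the RGB patch and produces p₁; the bridge multiplies the
input elementwise by p₁ (the canonical stacked form; channel
concatenation is available as `bridge="concat"`); U-Net 2 refines this
into the final map. Only the final output is supervised — a single dice
loss, no deep supervision. Two independent binary models (blue, red)
rather than one multi-class model keep the channels decoupled.

The engine is implemented directly on NumPy (float32, NHWC) with
manual backward passes, verified end-to-end against central finite
differences in float64. Convolutions are im2col + BLAS matmul; the
pack/scatter inner loops are numba-compiled (a pure-NumPy fallback
produces identical results). He initialization from a seeded
`numpy.random.Generator` makes two builds with the same seed
bit-identical; inference is deterministic (no dropout), and checkpoints
(NPZ weights + JSON config sidecar) round-trip to bit-identical
predictions.

**Training schedule.** Defaults mirror common practice (50 epochs,
batch 32). On a single CPU the effective budget is optimizer *steps*,
not epochs, so the bundled tests and the acceptance script train with
batch 8 for 4–6 epochs — several hundred Adam steps — which converges
on the synthetic task; epochs and batch size are ordinary estimator
parameters. No augmentation, no early stopping.

## Synthetic data: what it emulates, what it does not

`rishquant.synthetic` generates fields that emulate the geometry and
chromatics of duplex RNAscope at 40×: a pale background near RGB
(235, 225, 230) with low-frequency texture (coarse Gaussian grid,
σ = 6, bilinearly upsampled), blue dots near (60, 70, 150) and red dots
near (190, 60, 70) with ±15 uniform color jitter, drawn as filled
ellipses with radius uniform in [2, 5] px and ±30% axis jitter
(perfect circles would be trivially learnable), and additive Gaussian
pixel noise (σ = 5/255). Centers are rejection-sampled with a minimum
pairwise separation (default 12 px > 2 × max radius), which guarantees
by construction that connected components equal the requested count and
the two channel masks are disjoint; an `allow_touching` flag drops the
guarantee for stress tests. Placement failure after bounded retries
raises a "field too crowded" error. Masks are exact rasterizations of
the drawn ellipses (1 = dot, 0 = background; 0/255 on disk).

Cohorts draw one expression level per sample (uniform per-channel mean
ranges, defaults 10–90 blue / 5–45 red per field) and Poisson per-field
counts around it, with synthetic race/stage/Gleason labels for the
reporting demo. Every field's RNG derives from (seed, sample index,
field index), so cohorts are reproducible and parallelizable.

Passing tests on these fields demonstrates that the implementation
learns and counts correctly under the stated geometry; it does **not**
demonstrate robustness to real-tissue confounders — overlapping or
merged dots (no watershed splitting; merged signals count as one),
out-of-focus planes, stain variability, nuclei and cellular texture, or
scanner artifacts, none of which are simulated.

## Numerical and degenerate-input conventions

- Constant image in min–max normalization → all zeros, logged warning.
- Dice loss ε = 1 keeps the loss defined on empty patches; metric
  conventions for empty masks: both empty → DSC = IoU = precision =
  recall = 1; empty prediction vs non-empty truth → precision 1,
  recall 0, DSC = IoU = 0 (mirrored for the converse).
- IoU is reported from pooled pixel counts and satisfies
  IoU = DSC/(2 − DSC) to 1e−12.
- Batch aggregates are labeled **macro** (mean of per-field metrics)
  and **micro** (pooled tp/fp/fn); both are reported since either
  convention is common.
- Max-pool gradient ties route to the first maximum; batch-norm uses
  momentum 0.9 running statistics for inference.
- The train/test split, shuffling, and weight init all derive from the
  estimator seed; the pipeline fans one global seed out via
  `SeedSequence(seed).generate_state(3)` to synthesis and the two
  models.

## Problem sizes used by the bundled checks

Segmentation performance is assessed at a desk scale chosen for a
single CPU: ~800–1000 synthetic 64 × 64 patches (80/20 split), the
full-size depth-3/16-filter model, 5–6 epochs at batch 8; the
end-to-end cohort demo uses 3 samples × 10 fields of 256 × 256 px with
8-filter models. At these sizes the held-out pooled DSC of the blue
model exceeds 0.99 and per-sample mean counts are recovered within
max(1, 5%) per channel.

## Known limitations

- Touching/overlapping dots are counted as one component; the
  separation guarantee of the generator sidesteps this by default.
- CLAHE clip-limit semantics differ between common backends; the
  mapping used here (clip/256 on 256 bins) is documented above and
  configurable, but not identical to OpenCV's tile-grid definition.
- The NumPy engine is single-threaded and desk-scale; it is not a
  whole-slide inference engine.
- Scores above the 40-point reference ceiling are possible by
  arithmetic (10 × 5 = 50) and are flagged, not clamped; downstream
  consumers decide how to treat them.
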
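# rishquant

Segmentation, counting and scoring of duplex chromogenic **RNA in situ
hybridization (RISH)** micrographs, built around a patch-based **Double
U-Net** and the ordinal dot-count scoring rubric used for *HMGA2*
isoform profiling in prostate cancer tissue.

In duplex RNAscope-style RISH, each detected transcript appears as a
small chromogenic dot: blue (HRP substrate) for the wild-type *HMGA2*
isoform and red (AP substrate) for the truncated isoform. Pathology
workflows quantify these images two ways, and this package implements
both:

1. **AI-assisted quantification** — preprocess each field (min–max
   normalization to [0, 1], per-RGB-channel CLAHE with clip limit 2.0
   and 8 × 8 px tiles, 3 × 3 Gaussian blur with σ = 1.0), tile it into
   non-overlapping 64 × 64 patches, segment each chromogen with its own
   binary Double U-Net trained with dice loss
   (`L = 1 − (2Σpg + ε)/(Σp + Σg + ε)`), stitch patches back, clean the
   thresholded mask by morphological opening, and count dots as
   connected components (8-connectivity, minimum area 2 px). Masks are
   evaluated against ground truth with DSC, IoU, precision and recall.
2. **Manual-rubric scoring** — each 40× field gets an ordinal 0–5 score
   from its dot count (blue: 0 | (0,20] | (20,40] | (40,60] | (60,80] |
   >80; red: 0 | (0,10] | (10,20] | (20,30] | (30,40] | >40), ten
   fields are summed per sample (positive-control ceiling 40), and
   samples with wild-type score ≥ 4 or truncated score ≥ 3 count as
   positive. Group tables report mean ± SD by race, stage or Gleason
   pattern.

Because no public RISH image set accompanies this problem, the package
ships a **seeded synthetic field generator** (pale textured background,
elliptical blue/red dots of known position and count, pixel-exact
masks) that stands in for annotated slides everywhere: training,
evaluation and the end-to-end demo are fully reproducible offline.

The Double U-Net (two stacked encoder–decoder U-Nets with skip
connections; the second refines the first via an elementwise product
bridge, batch-norm + ReLU conv blocks, max-pool down / transposed-conv
up, sigmoid head) and its dice-loss Adam training loop are implemented
directly on NumPy — with numba-accelerated im2col kernels — so training a
desk-scale model needs no GPU or deep-learning framework.

## Worked example

```python
import numpy as np
from rishquant import (CohortSpec, SyntheticFieldSpec, generate_cohort,
                       DoubleUNetSegmenter, MorphConfig, PreprocessConfig,
                       binarize, morph_clean, count_dots, score_field)
from rishquant.pipeline import build_patch_dataset

fields, meta = generate_cohort(CohortSpec(
    n_samples=1, fields_per_sample=10,
    blue_mean_range=(40., 40.), red_mean_range=(15., 15.),
    field=SyntheticFieldSpec(height=256, width=256), seed=5))
X, yb, yr = build_patch_dataset(fields, PreprocessConfig())
model = DoubleUNetSegmenter(channel="blue_WT", depth=3, base_filters=8,
                            epochs=8, batch_size=8, seed=0).fit(X, yb)
print(f"held-out DSC {model.report_.test_metrics.dsc:.3f}")
cfg = MorphConfig()
for f in fields[:4]:
    prob = model.predict_field(f.image)
    n = count_dots(morph_clean(binarize(prob, cfg), cfg), cfg)
    print(f"{f.sample_id} field {f.field_index}: "
          f"{n} blue dots (true {f.true_blue_count}) -> score {score_field(n, 'blue_WT')}")
```

prints, after a couple of minutes of CPU training (seeds fixed):

```
held-out DSC 0.851
S000 field 0: 46 blue dots (true 46) -> score 3
S000 field 1: 45 blue dots (true 45) -> score 3
S000 field 2: 38 blue dots (true 39) -> score 2
S000 field 3: 33 blue dots (true 33) -> score 2
```

This compact 8-filter demo model is deliberately small: even at a
moderate pixel DSC the connected-component counts match the ground
truth to within one dot, and the rubric maps counts in (20, 40] to
score 2 and (40, 60] to score 3. The full-size model (16 filters,
~1000 patches, 6 epochs — what `scripts/acceptance.py` trains) reaches
a held-out pooled DSC above 99%.

The same stages are scriptable from a shell:

```bash
rishquant synth --out cohort/ --samples 3 --fields 10 --seed 1
rishquant train --channel blue --data cohort/ --out blue.ckpt --epochs 6 --batch-size 8
rishquant segment --model blue.ckpt --in cohort/images --out pred/
rishquant quantify --masks pred/ --out counts.csv
rishquant score --counts counts.csv --out scores.csv
rishquant report --scores scores.csv --meta cohort/metadata.csv --group race
rishquant run --seed 1 --out demo/        # all of the above in one go
```

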
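# Methods

`fstriage` re-creates, at desk scale, a triage pipeline for intraoperative
frozen-section whole-slide images (WSIs) of thyroid lesions. The clinical
problem: a binary benign/malignant classifier trained on the common subtypes
— papillary thyroid carcinoma (PTC) and nodular goiter (NG) — degrades on the
"rare" material every real sign-out stream contains (intermediate nodules
such as thyroid adenomatous lesions, TAL, and thyroid fibrous calcified
nodules, TFCN, plus low-incidence carcinomas and benign lesions). Rather than
pretending those slides do not exist, the pipeline routes them to a
pathologist: slides whose morphology does not look like a typical carcinoma
or a typical goiter are flagged *rare* and re-reviewed; the rest are
auto-diagnosed.

## Pipeline

1. **Tissue masking.** Otsu's threshold on the grayscale slide separates
   stained tissue (dark) from scanner background (white). A constant image
   yields an empty mask rather than an error.
2. **Patch sampling.** Training patches (256×256 by default at the working
   magnification) are sampled with exact class counts at a 1:3
   malignant:benign ratio, the same number from every slide. A patch is
   malignant iff its center pixel lies in the annotated lesion mask; every
   center lies in tissue and each patch must contain ≥25% tissue. Counts
   round as `floor(n/(1+ratio))` malignant, remainder benign.
3. **Segmentation.** A fully convolutional U-shaped encoder–decoder (skip
   connections, 2-class softmax head) is trained from scratch with softmax
   cross-entropy, batch size 32, initial learning rate 0.01, and exponential
   learning-rate decay (rate 0.94 per 1000 steps — the decay mechanism is
   standard; the constants are this package's defaults). The network is
   implemented in plain numpy (im2col convolutions, manual backpropagation,
   SGD with momentum 0.9) and deliberately small — 4 resolution levels, 8
   base channels — so CPU training on synthetic patches finishes in minutes.
   Supervision is per-pixel (the rasterized lesion-mask crop), which is what
   a softmax-cross-entropy U-Net implies. Because the network is fully
   convolutional, inference runs on 512×512 tiles regardless of the training
   patch size.
4. **Heatmap stitching.** Slides are covered by 512×512 tiles at stride 256
   over a frame padded by 128 px of background per border; only each tile's
   central 256×256 core is kept, discarding the margins where edge artifacts
   live. Cores partition the original raster exactly — this is checked
   exhaustively in the tests.
5. **Feature bank.** The heatmap is reduced to 69 named features in fixed
   order: per-lesion geometry (area mm², perimeter mm, diameter mm,
   eccentricity, extent, solidity — each aggregated over lesions by max, min,
   mean, sd, variance, skewness, kurtosis), heatmap intensity and
   gradient-magnitude statistics (the same moments plus histogram entropy and
   energy), grey-level co-occurrence statistics (contrast, dissimilarity,
   homogeneity, correlation, energy; heatmap quantized to 32 levels, distance
   1, four orientations averaged), Canny edge count and mean edge gradient,
   and the connected-region and lesion-pixel counts.
6. **Slide classifier.** A two-stage random forest: stage 1 is fit on all 69
   features, features are ranked by mean impurity decrease (permutation
   importance available behind a flag), the top 30 are kept, and stage 2 is
   refit on that subset. Defaults: 500 trees, unlimited depth, balanced class
   weights, fixed seed. The forest is fit on the train+val splits (common
   subtypes only, as in the source workflow).
7. **Triage.** An empirical decision tree over four interpretable
   quantities — the forest's malignancy probability and the maximum lesion
   area, diameter and perimeter — with division values 0.5, 300 mm², 7 mm and
   35 mm. Default topology: probability first; on the benign branch a slide
   is `common_benign` unless its maximum lesion area is implausibly large
   (≥300 mm², flagged `rare`); on the malignant branch it is
   `common_malignant` only when diameter ≥7 mm *and* perimeter ≥35 mm
   (typical invasive carcinoma with ragged edges), otherwise `rare`. The
   exact published branch layout is not recoverable from its description, so
   the topology is a configurable object; the default follows the stated
   sequential order (probability → area → diameter → perimeter) and the
   morphological rationale that malignant lesions carry large, irregular
   (high-perimeter) boundaries while benign nodules are round.
8. **Evaluation.** Ground truth for the three-way task is *relabeled*:
   TAL/TFCN are rare by definition; any other slide whose binary prediction
   disagrees with its label becomes rare; the rest keep their binary side.
   Reported metrics: 3×3 confusion, rare recall and precision, workload
   fraction (share of slides sent to re-review) and accuracy over the
   auto-diagnosed slides. Empty denominators give 0 by convention. AUC is the
   Mann–Whitney pairwise statistic with ties counted ½.

## Synthetic cohort

Clinical WSIs cannot ship with the package, so every stage is exercised on
generated slides: a white scanner background, a stained tissue blob (rotated
ellipse plus satellite fragments), lesions, and fibrotic-band streaks — the
pale elongated structures that drive false positives on real frozen
sections, rendered at an intensity between tissue and lesion so they act as
a genuine confounder for the trained segmenter.

Lesion boundaries are radial-harmonic perturbations of a disk,
r(θ) = r₀·(1 + Σ aₖ cos(kθ+φₖ)), scaled so the polygon area equals the drawn
target exactly; the summed amplitude Σ|aₖ| is the *boundary irregularity*
knob. Irregularity 0 gives a circle (perimeter within 5% of the equal-area
circle); at 0.35 the perimeter inflates by ≈34% on average, which is
precisely the feature the decision tree keys on. Multifocal slides draw one
dominant lesion from the subtype's area range plus satellite foci at 25–50%
of its area, as in multifocal carcinoma.

Default subtype phenotypes (areas per lesion):

| subtype  | lesions | area (mm²) | irregularity | fibrosis | binary label |
|----------|---------|-----------|--------------|----------|--------------|
| PTC      | 1–2     | 60–90     | 0.35         | 0.4      | malignant    |
| OtherTC  | 1–2     | 60–90     | 0.40         | 0.4      | malignant    |
| TAL      | 2–3     | 7–25      | 0.05         | 0.8      | malignant    |
| TFCN     | 2–3     | 8–25      | 0.08         | 0.8      | malignant    |
| NG       | 0       | —         | —            | 2.0      | benign       |
| OtherBTL | 0       | —         | —            | 2.0      | benign       |

The malignant phenotypes thus carry large, irregular lesions (equivalent
diameter ≈8.7–10.7 mm, typical perimeter ≥35 mm); the intermediates carry
small round nodules (diameter <7 mm, perimeter <20 mm) that land on the
malignant branch of the tree but fail its geometry test — which is exactly
how they end up flagged rare; the benign subtypes carry no tumor but dense
fibrosis. Slide subtype mixes default to the case-series prevalence (PTC
39.0%, NG 50.3%, TAL 5.2%, TFCN 3.3%, OtherTC 0.4%, OtherBTL 1.8%); cohort
splits place only PTC and NG in train/val/test1 and the rare subtypes in the
real-world test set (test2 ⊇ test1), mirroring the source study design.

**Physical scale.** `generate_slide` defaults to 2.0 µm/px (a 5×-equivalent
magnification at 0.25 µm/px native, ×8 — the native pixel size is a package
choice). Cohorts default to 32 µm/px: the triage thresholds are
clinical-scale (300 mm², 7 mm, 35 mm), and at 2 µm/px a 7-mm lesion needs a
≥3500-px raster, while cohort slides are capped at 1024² px for CPU budgets.
32 µm/px makes a 1024-px slide span 32.8 mm so that two ~10-mm lesions pack
into the tissue blob with placement slack. All features are computed in
physical units through mpp, so the pipeline itself is resolution-agnostic.

**Reproducibility.** One global seed fans out to per-slide seeds through a
fixed counter scheme (`SeedSequence((seed, index))`). An unlucky random
layout (lesions that cannot be placed without overlap) is redrawn
deterministically up to 5 times before an explicit placement error; requests
that can never fit fail immediately with that error.

## Oracle segmenter

To test the downstream stages independently of training quality, an oracle
predictor returns the ground-truth lesion mask as probabilities after (1)
flipping each connected component to negative with probability `flip_rate`
(emulating whole-lesion false negatives) and (2) adding pixelwise Gaussian
noise, then clipping to [0, 1]. Note the clipping halves the expected
absolute deviation on a binary mask: E|prob − mask| = σ/√(2π) ≈ 0.0399 at
σ = 0.1, because the out-of-range half of the noise is removed. The
end-to-end default `flip_rate = 0.05` was chosen analytically (before any
test run) so that a ~200-slide cohort contains about one fully suppressed
malignant slide — a missed rare slide, as in the source material — while
keeping expected rare recall ≈0.95 and common-subtype AUC ≈0.99.

## What the synthetic results do and do not show

Passing tests demonstrate that the machinery is correct and that the triage
logic behaves as designed when its assumptions hold: lesion-bearing slides
separate from lesion-free ones, intermediates are small and round, malignant
lesions are large and ragged. They do not certify performance on clinical
material: real frozen sections have nuclei-level texture, staining and
freezing artifacts, ambiguous lesion boundaries and annotation noise, none
of which the generator renders. The published headline numbers (AUC 0.986 /
0.946, recall 0.882, 33.4% workload) belong to 1,374 clinical WSIs that are
not distributable; this package reproduces their *arithmetic* from the
printed tables and mirrors their *qualitative* behavior on synthetic data
(repo-chosen bounds AUC ≥0.95, rare recall ≥0.85).

## Numerical conventions and edge cases

* Perimeter uses the Crofton (4-direction) estimator: on a rasterized
  100-px-radius disk it is within 0.3% of 2πr, while raw marching-squares
  contour length overestimates by ≈5%; the contour method remains available
  (`perimeter_method="contour"`). Diameter is the major-axis length of the
  second-moment ellipse.
* Heatmap binarization threshold 0.5; connected components use
  8-connectivity; components below 0.01 mm² are dropped as noise.
* Aggregates over fewer than 3 lesions set skewness/kurtosis to 0; a slide
  with no lesions gets all-zero geometry aggregates (never NaN). Intensity
  entropy is Shannon entropy (bits) of the 32-bin histogram; energy is the
  summed squared bin mass. A single-grey-level heatmap sets the
  co-occurrence correlation to 0. Flat heatmaps give (0, 0) Canny features.
* Patch sampling falls back to sampling with replacement (with a warning)
  when a slide has fewer eligible positions than requested.
* Tile grids pad with white background (probability 0 for oracle maps);
  statistics are only ever taken over the unpadded region.
* Precision and recall with empty denominators are defined as 0.
* Coordinates are 0-based, (row, col), half-open; ASAP-XML vertices are
  (X, Y) = (col, row) scanner order.

## Problem sizes

Defaults keep everything on one CPU core: the parameter-recovery cohort is
200 slides of 1024² px (≈115 in the real-world test split), oracle-segmented;
the end-to-end smoke run trains the U-Net on 160 patches of 64² px from a
12-slide cohort of 512² px slides. These sizes are the package's own test
conditions; all are configurable.
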
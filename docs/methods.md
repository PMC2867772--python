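# Methods

This note records the models, conventions and numerical choices behind
`oralscreen`, and what the synthetic phantoms do and do not establish.

## Data model and conventions

Pixel coordinates are 0-based `(row, col)`, row-major. Channel intensities
are reals in [0, 1]; 8- and 16-bit integer images are rescaled by their
dtype maximum so every feature is bit-depth independent. The data model is
resolution-agnostic: no assumption is made about sensor size or pixel
pitch. ROIs are boolean masks; polygon ROIs are rasterized by even-odd
fill with boundary pixels included (interior fill plus the drawn
perimeter), so an axis-aligned rectangle polygon equals the corresponding
mask exactly.

A site with an initial clinical impression of *abnormal* carries exactly
three observer impressions and a contralateral reference ROI; an initially
*normal* site carries neither. Records loaded from a manifest resolve
image/ROI paths relative to the manifest directory and load pixels lazily.

## Features

Twelve per-ROI metrics (see `features.FEATURE_FIELDS`). Two deliberate
conventions:

* **Two red/green ratios.** `mean_rg` is the mean of per-pixel R/G ratios;
  `mfi_ratio_rg` is mean(R)/mean(G). They coincide on constant images and
  differ otherwise. The headline "red/green MFI ratio" feature is the
  ratio of MFIs, matching how the feature is named in screening reports;
  both are computed and ranked.
* **Denominator guard.** Per-pixel ratios exclude pixels whose denominator
  channel is ≤ 1/255 (one 8-bit quantum); dark sensor noise otherwise
  produces unbounded ratios. If every ROI pixel is excluded the metric is
  NaN, flagged via a warning naming the site, and such sites are dropped
  from classifier fitting (again with a warning) — never silently zeroed.

Grayscale is BT.601 luma (0.299, 0.587, 0.114) — the standard conversion
for consumer RGB sensors. Standard deviations are population SDs (divide
by N): they are descriptive image statistics, and the fixed convention
makes results bit-reproducible.

### Normalization

`normalize_lesion` divides each lesion metric by the reference (contralateral)
metric. Identical numerator and denominator normalize to exactly 1 — this
covers the 0/0 case for the SD metrics of noiseless images and anchors the
identity "identical tissue ⇒ normalized metric 1". A zero reference with a
differing lesion value is undefined (NaN). All twelve metrics are
normalized uniformly, SDs included.

`normalize_by_split` (for sites without a contralateral ROI) orders the
ROI pixels along the longer bounding-box axis (ties → row axis), assigns
the first half — including the extra pixel for odd counts — to the
numerator, and ratios the two halves' feature vectors. The rule is
arbitrary but must be fixed for determinism. All mean-based normalized
features are invariant to global intensity scaling; this holds for the SD
features too.

Features are computed on both modalities; the default classifier candidate
set is the twelve *normalized fluorescence* metrics. Reflectance metrics
are computed and written to the feature table (column blocks `refl_`,
`norm_refl_`) but excluded from default ranking, reflecting that the
discriminative optical signal in this problem is autofluorescence loss and
red-shift; they can be selected explicitly.

## Adjudication

Majority of three observer impressions; unanimity and 2-of-3 are recorded
separately; all-distinct triples are excluded (24 of the 64 possible
triples). Initially-normal sites are categorized Normal without review.
Binarization: Cancer/HighRisk neoplastic, Normal/LowRisk non-neoplastic.
Melanosis sites are removed before feature selection by default; an
`include` mode exists to reproduce the confound (pigment-induced
fluorescence loss masquerading as neoplasia). OSF sites are retained as
non-neoplastic.

## Classification

The threshold sweep evaluates every unique score plus sentinels below the
minimum and above the maximum, so the ROC always contains (sens, spec) =
(1, 0) and (0, 1). Scores exactly at the threshold are predicted positive.
The sweep direction is chosen so the class with the higher mean is the
positive side; with a single input feature and equal-variance assumptions
a Fisher discriminant is monotone in the feature, so the sweep traces the
discriminant's ROC exactly.

AUC is trapezoidal over (FPR, TPR) sorted by FPR then TPR; this equals the
Mann–Whitney concordant-pair statistic with ties counted ½ (tested
exactly). The Q-point is the curve point minimizing Euclidean distance to
(0, 1); ties break toward higher sensitivity, then lower threshold. An
alternative sensitivity = specificity rule is available
(`--qpoint sens-eq-spec`). The stored model threshold is refined to the
midpoint of its decision interval (unchanged confusion matrix, boundary
strictly between neighbouring scores). Evaluation is in-sample by design —
the protocol being modelled develops and assesses on the same dataset, a
known over-training caveat.

Multi-feature models use the Fisher direction `(S_w + 1e-6 I)^{-1}(μ₁ − μ₀)`
with pooled within-class covariance; the ridge makes duplicated features
well-posed (a duplicated feature reproduces the single-feature AUC to
1e-9). Feature ranking sorts by descending AUC with alphabetical
tie-breaks.

Published clinical operating points for this class of device (normalized
blue MFI threshold 0.86 at 92 %/84 %; normalized red/green MFI ratio 1.11
at 90 %/87 %; an independent microscope study's 1.09) are embedded in
reports as documented reference metadata only.

## Synthetic phantoms

The generator emulates the qualitative optical structure of the screening
problem: homogeneous green fluorescence for Normal mucosa; progressive
green/blue fluorescence loss across Low Risk → High Risk; additional
orange-red gain for Cancer; melanosis as a multiplicative fluorescence
attenuation (0.55) under a dark reflectance patch; OSF as preserved,
slightly increased green (×1.02) under a pale reflectance patch.

Defaults: normal fluorescence means R/G/B = 0.15/0.60/0.30; design
normalized-green factors 1.0/0.90/0.75/0.60 and blue 1.0/0.85/0.65/0.50
across the four grades; red flat except a ×1.2 Cancer gain. These give
design normalized red/green ratios 1.0/1.11/1.33/2.0, placing the optimal
threshold for that feature near 1.1. All magnitudes are package design
choices — only the directions and approximate thresholds are constrained
by the clinical literature.

Noise has two components: i.i.d. per-pixel Gaussian noise (SD 0.02,
clipped to [0, 1]) and a per-site Gaussian offset (SD 0.10) added to each
fluorescence channel's design factor. The per-site component is essential:
pixel noise averages out over an ROI, so without it site-level features
would be nearly deterministic. It also gives the normalized channel MFI of
an abnormal category the approximate distribution N(design factor,
site_offset_sd), hence a closed-form expected AUC between two grades of
Φ(|g₁ − g₂|/(σ√2)) used as an analytic recovery check.

Dataset composition defaults to the 351-site clinical cell structure
(222/30/22/37 without confounders, 8/22 melanosis, 2/8 OSF); `--scale`
multiplies each cell with half-up rounding. Observer impressions are the
true category for all three observers, with probability 0.20 of one
observer deviating one grade (consensus unchanged) and, by default, zero
probability of a three-way disagreement so the composition stays exact; a
nonzero `all_disagree_prob` exercises the exclusion path. A single
explicitly-seeded RNG stream generates sites in a fixed order, making
datasets byte-identical across runs.

**What the phantoms do not show.** They contain no illumination-field
structure, specular glare, focus variation, anatomical geometry or camera
noise beyond Gaussian pixel noise, and their class separability is a design
choice: the default dataset yields AUCs of ≈ 0.79–0.998, higher than the
0.85–0.91 reported on clinical images. Passing tests demonstrate that the
pipeline's arithmetic, protocol logic and recovery behaviour are correct,
not that the clinical performance figures are reproduced.

## Problem sizes and determinism

Tests run the generator at 64×64 (default) or 32×32 frames; the analytic
AUC check uses 500 sites, the threshold-recovery check five random
configurations of 1000 sites, the confounder checks the full 351-site
default dataset — sizes chosen to make the statistical assertions sharp
while keeping the suite fast. All randomness flows from explicit seeds;
reports are serialized with sorted keys so identical configurations yield
byte-identical output. Images are written as 8-bit PNG; features computed
from re-read files are therefore quantized to 1/255, which is immaterial
at the effect sizes modelled.
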
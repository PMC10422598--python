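# Methods

This note documents the models, parameter choices and numerical conventions
behind `soyemerge`, and what the synthetic-data tests do and do not
demonstrate about real field imagery.

## Detection model

Seedling counting is classical image analysis, not learning: grayscale
transform → Otsu threshold → colour masking → 8-connected component
labelling → area filter → minimum bounding rectangles. One component is
counted as one seedling.

**Grayscale rule.** Default is excess green, `ExG = 2G − R − B` clipped to
[0, 255], because the targets are green foliage on brown soil; raw green
channel and ITU-R 601 luminance are available alternatives. All thresholds
below are on the chosen grayscale.

**Otsu implementation.** The between-class variance is evaluated in the
form σ²(k) = w₀(μ−μ₀)² + w₁(μ−μ₁)², where class 0 (target) is the pixels
strictly above k. This is algebraically equal to the more common
w₀w₁(μ₀−μ₁)² form, and the equality is asserted in tests. Conventions
pinned by tests: all 256 candidate thresholds are scanned; ties break to
the smallest maximising k; binarisation is strict (`gray > k`); a constant
image is flagged degenerate with σ² = 0. No morphological cleanup is
applied before labelling.

**Colour-image component analysis.** The binary mask retains the original
RGB (black elsewhere) and labelling runs on the non-black pixels of that
masked colour image. This reproduces a component pass "on the colour image"
without inventing a colour adjacency metric.

**Vegetation floor.** Otsu assumes both classes are present. On a bare-soil
image it happily splits soil noise and labels large spurious regions, so
`detect_seedlings` reports an empty scene whenever the target class's mean
grey falls below `min_target_gray` (default 60 on the ExG scale — soil noise
means sit below ~30, healthy foliage above ~120). This is the package's
guard against the known failure mode of thresholding vegetation-free
images; it also means genuinely sparse, weak-signal stands fail closed
(reported as no vegetation) rather than producing noise counts.

**Area filter.** `min_area` defaults to 25 px ≈ 1 cm² at the 2 mm/px
default ground sampling; it suppresses speck noise and small weeds. An
optional `max_area` can drop merged canopy blobs.

**Coordinates.** `(x, y) = (column, row)`, 0-based; rectangles are
`(x_min, y_min, width, height)` closed on both ends, so `width =
x_max − x_min + 1`.

## Crop dataset

Detections are expanded by a margin (default 10% of the rectangle size),
clamped, and resized bilinearly to 255×255×3; a window already at native
size passes through bit-identically. Labels are 0 = VE, 1 = VC, 2 = V1.

Augmentation operators and parameter ranges (all seeded draws):
brightness gain ∈ [0.7, 1.3]; horizontal flip; saturation factor ∈
[0.7, 1.3] (linear blend against luminance, so factor 1.0 is exact
identity); random crop retaining ≥ 80% area, resized back; scale ∈
[0.8, 1.2] with centre-crop or edge-replicate padding back to 255.

The dataset manifest stores augmentation *recipes* (source index, operator,
seed), not pixels; materialisation is deterministic on demand. Class
balance is achieved by augmentation multiplicity (default two copies per
original, so 1000 originals/class → 3000/class), with seeded top-up
augmentations when classes start unequal. The stratified 3:1 split floors
the test share and shuffles within class under the manifest seed.

## Growth-stage network

Architecture (all convolutions stride 1 with same padding):

| block | layers |
|---|---|
| 1 | conv 7×7 → ReLU → LRN → max-pool 3×3 stride 2 |
| 2 | conv 5×5 → ReLU → LRN → max-pool 3×3 stride 2 |
| 3–4 | conv 3×3 → ReLU (twice) |
| 5 | conv 3×3 → ReLU → max-pool 3×3 stride 2 |
| head | flatten → FC 1024 + dropout 0.6 → FC 256 + dropout 0.6 → FC 3 softmax |

At 255×255 input the spatial chain is 255 → 127 → 63 → 31. Overlapping
pooling (window 3 > stride 2) and LRN follow the classic AlexNet recipe;
LRN uses window 5, α = 1e-4, β = 0.75, k = 2. Loss is softmax
cross-entropy; ties in the argmax resolve to the lowest class index;
dropout is inverted and disabled at evaluation, so inference is
deterministic.

**Channel widths.** The conv channel counts are configurable because no
single published width is canonical for this variant; the full-scale
default is (32, 64, 96, 96, 64). `NetConfig.desk_scale()` keeps the
architecture but narrows to (2, 4, 6, 6, 4) (≈ 4.2 M parameters), sized so
the network trains in minutes on one CPU.

**Optimisation.** Adam with the full-scale defaults: learning rate 1e-4,
batch 32, dropout 0.6, 150 epochs. `TrainConfig.desk_scale()` raises the
learning rate to 1e-3 and trains 20 epochs: a narrow net on a few hundred
optimiser steps needs a larger step size, and the value was fixed from a
short probe on solid-colour separable data. Weight init is He-normal from
a seeded generator; shuffling and dropout masks derive from the training
seed, so a fixed seed reproduces the run exactly (single-threaded).

**Implementation.** Forward and backward passes are written on float32
NumPy arrays. Convolution, LRN window sums and overlapping pooling run as
Numba-jitted fused loops in channel-first layout (contiguous inner rows);
a pure-NumPy fallback path produces identical results (asserted in tests)
when Numba is unavailable. Layers reuse shape-keyed scratch buffers across
steps — repeated multi-megabyte allocations, not arithmetic, dominate
runtime otherwise on a single-CPU machine.

**Metrics.** Average loss AL = e_L/e and average accuracy AA = (e_A/e)×100%
summarise the per-epoch *test* loss/accuracy trajectory over e epochs (so
AA lags final accuracy early in training); model accuracy A = N_C/N_T with
a per-class breakdown and confusion matrix.

## Emergence reporting

EP_i = TP_i/ST per stage; proportions sum to 1 whenever any seedling
emerged; an empty field yields a defined "no proportions" report.

R² is the standard coefficient of determination
1 − Σ(y−ŷ)²/Σ(y−ȳ)², flagged undefined (None) when the manual counts have
zero variance. RMSE and MAE follow their usual definitions. "Average
accuracy" is the mean over sites of (1 − |ŷ−y|/y)×100, with zero-truth
sites excluded from the mean and counted separately.

Uniformity is codified as three configurable rules: a stand is uniform when
the dominant stage's proportion ≥ θ_dom (default 0.90); it is non-uniform
when all three stages each hold ≥ θ_coexist (default 0.05, "multi-stage
coexistence") or when the emerged total is below θ_density (default 0.5) of
an expected plant count ("low emergence"). Raising θ_dom is monotone: it
can only move verdicts from uniform to non-uniform.

## Synthetic scenes

The generator emulates the acquisition conditions the pipeline is designed
for: ridge planting with rows 225 mm apart, plant spacing 71 ± 8 mm along
the row, 2 mm/px ground sampling (one plant ≈ 35 px), brown soil with
Gaussian noise, a multiplicative illumination ramp, and per-stage plant
morphology — VE one compact cotyledon blob, VC two opposed lobes joined by
a hypocotyl bridge, V1 cotyledons plus a trifoliolate cluster, with a mild
stage-dependent green shade (VE yellower, V1 darker, as cotyledons differ
from true leaves). Distractors are elongated bright shapes with low excess
green, mimicking light-reflecting corn stalks. With overlap disabled,
footprints are kept disjoint with a one-pixel gap so 8-connectivity cannot
merge neighbours; ground truth records every footprint pixel exactly.

What the synthetic tests show: the detection chain recovers exact counts
when its assumptions hold (green-dominant plants, bimodal grayscale,
separated plants), distractors below the green threshold never perturb
counts, and the classifier can learn the documented morphology signal.
What they do not show: robustness to real-field texture, specular
highlights, weeds with plant-like colour, motion blur, or canopy overlap at
later stages — the generator's plants are procedural composites, not
photorealistic.

## Problem sizes

The test suite trains the desk-scale network for 20 epochs on 900 separable
synthetic crops (675/225 split) and exercises counting on 50 generated
scenes of ~70 plants each. The acceptance script uses 30 scenes for count
evaluation, ~500 detected crops (augmented ~2×) with 12 training epochs for
the classifier, and 4 held-out scenes for the end-to-end proportion error.
These sizes were chosen so a complete run finishes in minutes on one CPU
while every quantity is still computed from scratch.

## Known limitations

- Counting is resolution-dependent: the area filter and vegetation floor
  assume roughly 2 mm/px; other ground samplings need rescaled thresholds.
- Overlapping plants merge into one component (counts are a lower bound as
  density grows); no instance segmentation is attempted.
- The vegetation floor trades sparse-stand sensitivity for robustness on
  vegetation-free images.
- The classifier is trained per-deployment; no pretrained weights ship with
  the package.
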
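# Methods

This note records the model behind each stage of the pipeline, the
parameters that matter, and what the synthetic test bed does and does not
demonstrate.

## Subjective scoring

Each rater scores five parameters (color, distribution, depth, elasticity,
roughness) with integers 0–3; a rater's sum lies in [0, 15] and the photo's
*average of sum* is the mean over raters. The printed category bands
(mild 1–4, moderate 5–9, severe 10–15, invalid ≤ 1) are integer labels; we
map fractional averages with half-open intervals — invalid (−, 1],
mild (1, 5), moderate [5, 10), severe [10, 15] — which preserves every
integer assignment and makes values such as 4.5 well defined (4.5 is mild).
Averages are stored at full precision and displayed at two decimals.

## Skin segmentation and the SGR window

A pixel is skin-colored when its full-range YCbCr chroma falls in the
classic box Cb ∈ [77, 127], Cr ∈ [133, 173] (config-overridable). The
largest connected component is kept and holes (navel, specular spots)
filled. The navel coordinate is an input, not detected.

The *striae gravidarum region* (SGR) is the largest square centered on the
navel inside the skin mask's bounding box. With bounding box
(x0..x1, y0..y1) and navel (nx, ny) the side is
`2 · min(nx − x0 + 1, x1 − nx, ny − y0 + 1, y1 − ny)` — always even, with
the navel at local index (side/2 − 1, side/2 − 1), 0-based, x rightward,
y downward. The navel row and column belong to the lower/right quadrants.
Grayscale conversion uses ITU-R 601 luma weights so results are
bit-reproducible.

## Binarization into skin (R_S) and striae (R_SG)

The grading methodology prescribes only "binarization with an adaptive
threshold", so the concrete rule is ours:

1. Gaussian pre-smooth (σ = 1 px) to keep sensor noise out of the striae
   class.
2. Local mean over a square window of side max(15, SGR/8) px (forced odd) —
   scale-free in image resolution.
3. Dead zone: pixels within δ = 4 gray levels of the local mean are
   skin-like. A plain zero-offset local-mean threshold necessarily bisects
   noise-only skin into two half-populations, which would report ≈ 50%
   striae density on striae-free skin and saturate the quadrant statistic;
   the dead zone is what makes "no striae → density 0" true.
4. The below-mean and above-mean classes outside the dead zone compete:
   the class whose mean gray lies farther from the overall SGR mean becomes
   the striae side. This distance rule (rather than "darker = striae") makes
   the partition symmetric under gray inversion: bright striae on darker
   skin are segmented identically.
5. A two-means iteration on the deviation image then refines the threshold
   to the midpoint of the striae and skin class means. Because a smoothed
   step edge crosses its half-amplitude exactly at the true edge, this
   places the boundary at the sub-pixel edge location and keeps pixel counts
   unbiased (≤ 1% error on rendered bands, versus ≈ +1 px per stripe side
   without it).

Degenerate inputs: a uniform window yields an empty R_SG with
g_SG := g_S, so C = D = 0. **Known limitation:** when striae genuinely
cover more than half of the window, "the class farther from the mean" is
the minority class — actual skin — and the labels invert. Any rule that is
symmetric under gray inversion has this ambiguity; the grading method is
meaningful for striae coverage below one half, and the synthetic cohorts
cap per-quadrant coverage at 0.49.

## Objective parameters

- **C = |G_SG − G_S| / 255** and **D = N_SG/(N_SG + N_S)** follow directly
  from the partition.
- **W = 2 · N_SG / N_e** with N_e the count of Canny edge *pixels* (not
  contours): for band-like shapes, area over half-perimeter is the width,
  so W is a mean stripe width in pixels. Canny runs at σ = 1.4 with
  hysteresis thresholds at 0.1/0.2 of a robust gradient scale — the 99.5th
  percentile of the gradient magnitude rather than the maximum, so that one
  strong gradient (the navel) cannot mask faint stripe edges — and never
  below 4× a noise floor estimated from the 20th gradient percentile under
  a Rayleigh model of the noise response. The gradient is computed exactly
  as the Canny implementation computes it internally (unnormalized Sobel of
  the smoothed image) so thresholds live on the right scale. W = 0 when no
  edge rises above the floor.
- **A = 0.25 · N** where N counts navel-centered quadrants whose striae
  density strictly exceeds the empirical cut-off 0.4; a quadrant at exactly
  0.4 does not count.
- **E** is the Cutometer R2 total-elasticity index, the third value of a
  10-value R0..R9 record; values outside [0, 1] pass through with a
  warning. A missing record leaves E flagged missing — never imputed — and
  classifier configurations that use E refuse such rows.
- For treatment series (≥ 2 photos of one patient), each parameter is
  min–max normalized over the series to [0, 3], with E inverted first
  (higher elasticity = healthier = lower severity score); a constant
  parameter contributes 0; the per-photo sum and its series average mimic
  the subjective score scale.

## Severity classifier

The linear-kernel SVM is authored in-package. The dual problem
(soft-margin box 0 ≤ α ≤ C, default C = 1) is solved by deterministic
pairwise updates: the first working index is the most violating one, the
partner maximizes the guaranteed second-order objective gain, and the
solver stops when the KKT gap falls below 1e−6 (iteration-capped).
Incremental gradients are refreshed every 2000 iterations; degenerate duals
— a middle class versus the rest is not linearly separable, and its exact
optimum can be w ≈ 0 with every α at the bound — can crawl with the gap
stuck at rounding scale, so a numerically stationary objective with
residual gap < 1e−3 is accepted as converged. On small problems the solver
matches a generic quadratic program (scipy SLSQP on the same dual) to
≈ 1e−7 and the closed-form two-point solution exactly; those references are
used only as test oracles.

Features are standardized to train-set mean/SD before the dual solve (W is
in pixels while C, D, A, E live in [0, 1]). Multiclass is one-vs-rest with
the maximal decision value; exact ties go to the earliest class in
mild < moderate < severe order. Stratified splits put round(0.8 · n) of
each class in training — the unique rounding consistent with the published
counts 64/80, 61/76, 69/86. Recognition rate is 100 · correct/tested,
reported to two decimals. The ablation harness evaluates the five standard
subsets (C+W+A, C+D+A, C+D+W, C+D+W+A, all five) with split seeds shared
across subsets, so subset comparisons are paired.

## Synthetic cohorts — what they emulate and what they do not

Photos are rendered as a fixed skin chroma (full-range YCbCr Cb = 110,
Cr = 150, inside the detection box) whose luma carries all structure:
Gaussian sensor noise (SD 3), a small dark navel disc, and hard-edged wavy
stripe bands (sinusoidal axis perturbation, default amplitude 2 px, period
64 px). Hard edges mean coverage, per-quadrant density and mean run width
are exact pixel counts, which is what makes the D/W/A oracles possible.
The default image side is 512 in no way sacred; 256 px is used throughout
the tests and the study scripts as a speed/fidelity compromise (the
thresholding window scales with the image, so features are
resolution-robust).

The three severity profiles draw, per photo: the number of striped
quadrants (mild 1–2, moderate 2–3, severe 3–4), per-quadrant target
coverage (0.20–0.42 / 0.36–0.50 / 0.42–0.49), stripe width (3–6 / 5–9 /
8–12 px), gray contrast (10–26 / 22–42 / 38–62), and the elasticity index
R2 (normal with means 0.86 / 0.81 / 0.79 — the reported per-group averages
— and SD 0.008). Adjacent classes overlap in every single feature, so no
one parameter classifies alone (consistent with the clinical observation
that motivated the multi-parameter design), while the classes are far
apart jointly: adjacent class means sit ≈ 5 pooled within-class SDs apart
(Mahalanobis), recognition with all five features runs 95–97%, and each
feature carries partly independent information, which is why adding
features does not lower the mean recognition rate.

What passing tests do **not** show about real photographs: real skin has
texture, uneven illumination, hue variation along the healing trajectory,
hair and occlusions — none of which are modeled. The synthetic cohorts
validate the *implementation* of the operators and the *internal
consistency* of the methodology (formulas, ordering patterns, split design,
solver), not clinical accuracy. The clinical photo collection behind the
original study is not shared, so its absolute recognition rates cannot be
reproduced here and are explicitly out of scope.

## Numerical conventions worth knowing

- Quadrant split: the navel pixel is the shared corner; its row/column go
  to the lower/right quadrants; empty quadrants have density 0.
- A-threshold comparison is strict (">"), tested at densities of exactly
  0.4.
- Split rounding uses Python `round`; 0.8 · n never lands on .5 for
  integer n, so banker's rounding never engages.
- All randomness flows through `numpy.random.default_rng` seeds threaded
  explicitly; identical spec + seed reproduce images bit-for-bit, and the
  pipeline (simulate → features → evaluate) is byte-deterministic under a
  fixed seed.
- The elasticity CSV, manifest, feature table, score sheets and reports are
  plain CSV; models persist as JSON (weights, bias, multipliers, scheme,
  standardization constants, feature subset).
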
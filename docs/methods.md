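# Methods

`reefquad` implements a complete photoquadrat monitoring pipeline for
shallow reef benthos: image preparation, point-count annotation with
confidence gating, percent-cover estimation, beta-GAM temporal trend
models, and community-level ordination. This note records the models,
their assumptions, the tunable parameters, and the design decisions made
where the field's practice leaves the choice open.

## Synthetic scenes and the cover generator

All verification runs on synthetic inputs with known truth.

**Scenes.** A quadrat scene is a mosaic of spatially coherent patches,
built from a seeded Voronoi tessellation (default 60 cells) whose cells
are assigned to benthic classes. Class pixel counts over the frame
interior are made *exact* (to integer rounding) by ordering interior
pixels by shuffled cell and within-cell distance-to-seed, then cutting
the ordering at the requested counts: at most one cell per class boundary
is split, and the split piece is a coherent disc around its seed. This
lets ground-truth interior fractions serve as tight oracles
(`1/min(width, height)` tolerance) while keeping the patchy spatial
structure that point sampling must see. Degradations are applied after
composition: a near-white (≥ 240 pre-cast) frame band of configurable
thickness rotated by up to ±20°, additive green/blue channel offsets, and
a multiplicative overexposure gain ≥ 1. The label map is never touched by
color degradations.

What the scenes do *not* emulate: photographic texture within organisms,
depth-dependent attenuation, lens distortion, perspective keystone, blur,
or partial frame occlusion. Passing image-stage tests therefore
demonstrate geometric and radiometric correctness of the operators, not
robustness to every field pathology.

**Cover series.** Per-image proportional cover for a label is drawn from
Beta(μφ, (1−μ)φ) with

logit μ = logit(baseline) + slope · (year − ȳ) + b_site,
b_site ~ N(0, σ_site²),

on the survey calendar (2014, 2016–2019 by default). Defaults: baseline
0.10, precision φ = 30, σ_site = 0.5 (logit scale) — site-to-site spread
and within-site-year scatter of the magnitude routine reef photoquadrat
data show. Slopes are per-label and may differ by reef type, which is how
reef-type-specific trends are injected for power studies. The generator
is the same inverse-logit beta model the trend stage assumes, so
parameter-recovery tests are exactly that; they do not probe
misspecification (zero inflation, temporal autocorrelation on fixed
transects, spatial correlation along a transect).

## Frame rectification

Detection thresholds near-white pixels (default ≥ 200 on the per-pixel
channel minimum), keeps the largest connected component, and estimates
the frame angle as the rotation in [−20°, 20°] minimizing the
component's axis-aligned bounding-box area (coarse 0.2° grid, then a
0.01° refinement) — a rectangle's bounding box is smallest when
axis-aligned, so no moment or Hough machinery is needed and hollow
square bands (which defeat second-moment orientation estimates) are
handled naturally. The crop region is the largest connected interior
hole of the rotated band, shrunk by a 2 px safety margin so interpolation
blur from the bilinear rotation (reflective edge padding) never leaks
band pixels into the crop. Detection confidence is the fraction of the
fitted rectangle perimeter (offset 4 px into the band) covered by bright
pixels; below `min_band_fraction` (default 0.6) the image is declared
frameless, the correct outcome for later survey years that dropped the
PVC frame. A rotation of exactly 0 takes a pure-crop path that is
bit-exact.

## Color balance

The corrector is deliberately the simplest operator consistent with its
purpose: R′ = R + α · (Ḡ + B̄)/2 per pixel (a constant, per-image
additive red shift; default α = 0.3), then all channels scaled by 1 − β
(default β = 0.1), rounding half-up and clipping to [0, 255] after each
step, in 8-bit sRGB with no gamma linearization. The additive (rather
than multiplicative) red shift is the most literal reading of "raise red
in proportion to the average green and blue"; both constants are recorded
alongside outputs so any chosen correction is reproducible.
`cast_reduction_score` measures the change in |R̄ − (Ḡ+B̄)/2| and is
signed so that red overshoot is detected, not rewarded.

## Annotation and confidence gating

25 points per image (the monitoring protocol's density) are drawn
uniformly *without replacement* at pixel granularity — duplicate points
add no information. The machine/human split uses a threshold of 0.5 on
machine confidence with ties going to the machine (the boundary case is
genuinely ambiguous in practice; ≥ is the chosen convention, and the
threshold is a parameter). Overall confidence of a finished image is the
mean machine confidence with manually scored points counted at 1.0 — the
only convention under which human completion raises the figure, as it
should.

The simulated classifier reproduces ground truth with probability
`accuracy` (default 0.85) and otherwise picks a uniformly wrong benthic
label; confidence is Beta(28, 2) on correct calls and Beta(4, 4) on
wrong ones. These defaults describe a classifier that is confident when
right and uncertain when wrong, and place the gated auto+manual workflow
at ≈ 92% overall confidence with ≈ 7% of points routed to a human — the
operating point of a trained annotator in routine reef monitoring.

Annotation tables use the common machine-annotation CSV dialect (Name,
Row, Column, Label, Machine confidence; UTF-8 with header). The dialect
does not persist auto/manual status, so imports infer it from the gate.

## Cover statistics

Quality points (shadow, transect tape, unidentifiable) are removed and
the denominator renormalized to the remaining benthic points, so
per-image benthic cover always sums to 1; an image left with no benthic
points is flagged, never silently dropped. Site-year aggregation averages
over images with SE = sd/√n_images — the image is the replication unit.

The oversampled-year fix subsamples n = 20 distinct images without
replacement, computes per-label means, and reports the per-label median
over 1000 iterations. Images are put in canonical id order first so the
procedure is invariant to input row order. Per-label medians need not sum
exactly to 1 and are reported as-is.

The area-bias check regresses per-image cover on log10 image area (m²)
by OLS for every label above 1% mean cover. It is a diagnostic for
surveys whose pre-standardization images captured varying areas: a null
outcome licenses using raw covers.

## Temporal trend model

Observed proportions are squeezed off the boundary with
p* = (p(n−1) + 0.5)/n, where n is the number of rows entering each
model (recorded in the fit); p* is strictly inside (0, 1), monotone, and
fixes 0.5. The trend model is a beta-family GAM with logit link:
parametric reef-type effect, a global smooth of year, a deviation smooth
of year per non-reference reef type, and a random-intercept term for
locality. Numerics are delegated to mgcv (REML, via `Rscript`, batched
so simulation studies cost one engine start); the boundary transform,
model assembly, prediction post-processing and all calibration machinery
are native.

Two choices deserve emphasis:

- **Deviation smooths, not one smooth per level.** A global year smooth
  plus one smooth per reef-type level is rank-deficient in the
  unpenalized (linear) directions — year equals the sum of its per-type
  copies — and in simulation that structure produced by-term type-I
  errors of 17–23% and smeared a forereef-only trend across both types.
  The ordered-factor deviation parameterization (global smooth = trend of
  the reference type, here patch; one deviation smooth per other type) is
  identifiable, calibrated, and answers the same questions: the
  forereef deviation smooth tests whether forereefs depart from the patch
  trend.
- **Fixed-df year smooths by default.** With only five distinct survey
  years (k = 5 basis, never more than the number of distinct years),
  penalization has essentially no room to act, while smooth tests
  conditional on REML-estimated smoothing parameters ran measurably
  liberal in null simulations (6.6–7.9% at nominal 5%). Fixed-df
  regression splines (`fx=TRUE`, k − 1 df Wald chi-square tests) restore
  accurate size (≈ 5–6%) at no practical cost to the fitted curves;
  `penalized=True` restores REML smooths for users with longer series.

Fitted curves are reported on the response scale with 95% intervals from
±1.96 link-scale SEs, excluding the locality random effect (the curve of
a typical site). Single-locality data drop the random effect with a
flag; non-convergence raises with engine diagnostics; deviance residual
summaries ship in every fit for assumption checking. The fixed-transect
sensitivity refit filters to fixed-transect sites (by `transect_type`
column, else the default roster) and drops reef-type terms, since a
single reef type remains by design.

## Community ordination

Site-year mean covers are square-root transformed into a site-year ×
group matrix. NMDS runs on Bray–Curtis dissimilarities (the
community-ecology default; Euclidean available) through scikit-learn's
non-metric SMACOF with 20 seeded restarts, 300 iterations, and a 1e-6
relative stress tolerance, reporting Kruskal stress-1 with the
conventional reading (< 0.1 excellent, 0.1–0.2 good to excellent,
> 0.2 poor). Zero-dissimilarity rows coincide only in the optimization
limit; tests of that property run the optimizer to convergence.

RDA is native: terms (default reef type, locality, year-as-factor) are
added sequentially as orthonormalized design blocks; each term's
statistic is the pseudo-F of the variance it adds against the full-model
residual, and significance comes from unrestricted permutation of the
centered response rows, p = (1 + #{F* ≥ F})/(1 + n_perm) with
n_perm = 999 by default (minimum attainable p = 1/1000). Locality nests
reef type, so ordering matters: placed after reef type, locality carries
the within-type site variance; a term adding no independent columns
raises an error naming the aliasing. Rows are kept in canonical
(site, year) order so the seeded permutation stream makes p-values
invariant to input row order. The total-variance identity (constrained +
residual = total) is maintained to 1e-8 and asserted in tests.

## Problem sizes in the test suite

Calibration checks use sizes chosen to make their binomial noise small
relative to the bands they assert: 2000 null replicates (6 sites × 5
years × 5 images) and 200 power replicates (× 20 images, the survey's
density) for the GAM; 800 null replicates at 999 permutations for the
RDA; 500 replicates at the survey's n = 42 for the area regression; a
9-angle × 20-seed sweep for frame recovery. The acceptance script
recomputes the same quantities at moderately reduced replicate counts.

## Known limitations

- Frame detection assumes a bright, mostly unoccluded rectangular band;
  heavy overexposure can push benthos past the brightness threshold, and
  non-rectangular or broken frames are out of scope.
- No perspective or lens-distortion correction: the frame is squared by
  pure rotation.
- The color balancer is an annotation aid, not a radiometric correction;
  it operates on raw 8-bit values with no attenuation physics.
- The beta model treats observed cover as continuous; with 25 points an
  image's cover is really a scaled count, and the boundary squeeze is a
  pragmatic, not generative, fix.
- The RDA permutes rows freely; no temporal blocking is applied, so its
  year test assumes exchangeable site-year units under the null.
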
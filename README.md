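# reefquad

A toolkit for photoquadrat-based monitoring of reef benthos, written for
monitoring programs that photograph fixed areas of seafloor along
transects and need to turn thousands of images into defensible cover
trends. It covers the full pipeline:

1. **Scene simulation** — synthetic photoquadrats (Voronoi-patch benthos,
   PVC frame at a known rotation, green/blue cast, overexposure) and
   beta-distributed cover time-series, all with exact ground truth, so
   every later stage is testable without field data.
2. **Frame rectification** — detect the bright quadrat frame, rotate the
   image so the frame is square with the edges, crop to its inside edge.
3. **Color balance** — raise the red channel in proportion to the mean
   green/blue level and damp overall brightness, the standard quick fix
   for underwater color cast and overexposure.
4. **Point annotation** — random points per image (default 25), a
   machine label + confidence per point, auto-scoring at ≥ 50%
   confidence and a manual queue below it, CoralNet-style CSV in/out.
5. **Cover statistics** — per-image and site-year percent cover (quality
   labels excluded, denominator renormalized), the n = 20 × 1000-iteration
   resampling-median fix for oversampled years, and an image-area bias
   regression.
6. **Trend models** — proportions squeezed off the boundary with
   *p\** = (*p*(*n*−1)+0.5)/*n* and fit with a beta-family GAM
   (logit link): reef-type effect, global year smooth, per-reef-type
   deviation smooths, locality random intercept (mgcv engine).
7. **Ordination** — square-root cover matrix, Bray–Curtis NMDS with
   stress, and a native RDA with a 999-permutation ANOVA.

Image-stage and model-stage components are scikit-learn-style estimators
(`FrameRectifier`, `ColorBalancer`, `SimulatedPointClassifier`,
`BetaTrendGAM`, `NMDSOrdination`, `RDAPermutationANOVA`); the module
functions are thin wrappers over them. See `docs/methods.md` for the
models, assumptions and design decisions.

## Worked example

```python
import reefquad as rq
from reefquad.cover import image_cover

spec = rq.SceneSpec(
    class_fractions={"SC": 0.15, "MA": 0.15, "CS": 0.45, "SAND": 0.25},
    frame_rotation_deg=7.0, cast_green=35, cast_blue=20, seed=1,
)
img, truth = rq.render_quadrat(spec)

det = rq.detect_frame(img)
print(f"frame correction: {det.rotation_deg:+.2f} deg (confidence {det.confidence:.2f})")
quad = rq.rectify_and_crop(img, det)
print(f"cropped to {quad.shape[1]}x{quad.shape[0]} px; "
      f"frame contamination {rq.frame_contamination(truth, det):.4f}")

alpha = rq.auto_alpha(quad)   # closed-form red gain for this image
balanced = rq.balance(quad, rq.BalanceParams(alpha=alpha, beta=0.1))
print(f"red gain {alpha:.3f}; cast change {rq.cast_reduction_score(quad, balanced):+.2f}")

pts = rq.generate_points(balanced, 25, seed=2)
drafts = rq.simulated_classifier(pts, truth, seed=3, image_id="quadrat_0001")
auto, queue = rq.gate_annotations(drafts, threshold=0.5)
final = auto + rq.manual_from_truth(queue, truth)
print(f"{len(auto)} auto-scored, {len(queue)} manual; "
      f"overall confidence {rq.overall_confidence(final):.3f}")
print(image_cover(final).to_string(index=False))
```

prints

```
frame correction: -6.99 deg (confidence 1.00)
cropped to 226x226 px; frame contamination 0.0000
red gain 0.025; cast change -3.51
23 auto-scored, 2 manual; overall confidence 0.902
label    cover  n_points_included
   CS 0.608696                 23
 SAND 0.130435                 23
   SC 0.086957                 23
   MA 0.086957                 23
  LTA 0.043478                 23
   SP 0.043478                 23
```

The 7°-rotated frame is recovered to 0.01°, the crop contains no frame
pixels, the closed-form red gain reduces the measured green/blue cast
(negative change), 23 of 25 points clear the 50% confidence gate, and
with two transect-tape points excluded the benthic covers are fractions
of the 23 remaining points, summing to 1.

Simulated cover series feed the trend and ordination stages the same way:

```python
df = rq.simulate_cover_series(
    6, trend={"SC": {"patch": 0.0, "forereef": 0.25}}, seed=7, n_images=20
)
fit = rq.fit_trend_gam(df)           # term tests, deviance explained, curves
m = rq.build_matrix(df.groupby(["site", "year", "reef_type", "label"],
                               as_index=False)["cover"].mean())
res = rq.rda_perm_anova(m, n_perm=999, seed=0)
```

A `reefquad` command-line tool wraps the pipeline for directory-level
work (`reefquad simulate / rectify / balance / points / score /
confidence / cover / trends / ordination`); each subcommand writes plain
CSV/PNG/JSON artifacts.

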
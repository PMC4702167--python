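# Methods

This note documents the models and procedures implemented in `eggstage`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic benchmark does and does not show.

## Segmentation model

A cropped midsagittal DAPI section contains one egg chamber: bright
nuclei on a dark background. The chamber is isolated in five steps.

**Scaled Otsu binarization.** Otsu's threshold maximizes between-class
intensity variance; nuclei brightness spans an order of magnitude, so the
working threshold is `otsu_scale` × Otsu (default 0.2). The low scale
keeps dim nuclei at the cost of admitting noise, which later steps remove.
Intensities are first rescaled to [0, 1] by the dtype maximum so the
scale is calibration- and bit-depth-independent.

**Average filter + re-threshold.** A mean filter over a square window
turns the binary image grayscale; re-thresholding with plain Otsu fuses
the chamber's nuclei into one connected region while sparse noise stays
fragmented. The window must bridge inter-nucleus gaps, which are a
*physical* length, so the default is expressed as `filter_window_um` =
15 μm and converted per image calibration (clamped to odd 5–31 px); a
fixed pixel window can be forced via `filter_window`. At a typical
confocal calibration near 1 μm/px this reproduces a 15-px window.

**Largest component, hole filling, masking.** 8-connected components
(ties broken toward the first label in raster order); the largest is the
chamber because the chamber dominates a cropped image. Its filled mask
gates the original intensities.

**Chan–Vese nuclei.** The active contour minimizes boundary length (μ =
0.25) plus intensity-fidelity terms (λ₁ = λ₂ = 1), 200-iteration cap,
tolerance 1e-3. Initialization is a deterministic grid of circles
(radius 3 px, spacing 8 px) kept only over candidate foreground — pixels
above the initial threshold inside the chamber mask. Restricting the
seeds matters twice: circles seeded uniformly give the two regions equal
initial means, from which the contour can collapse to nothing, and
circles in the large flat oocyte void can survive as spurious foreground.
The energy depends only on region means, so results are invariant to
adding a constant to all intensities, and everything is deterministic.
The contour is evolved on the chamber's bounding box only (the exterior
is exactly zero), purely for speed.

**Convex hull.** Chamber size is the rasterized convex hull of the nuclei
pixels: a pixel belongs to the hull if its center satisfies every hull
half-plane inequality (tolerance 1e-9). This rule makes rasterization
idempotent — the hull mask is its own convex hull — and area is pixel
count × `pixel_size`². Area is reported in μm², which makes chambers
acquired at different magnifications directly comparable.

## Shape, orientation, features

**Aspect ratio.** PCA of the hull-interior pixel coordinates gives the
major/minor axes; the ratio of projected standard deviations σ₁/σ₂ is the
chamber ratio. SDs integrate over the full interior, so a localized
boundary defect of a few percent of area barely moves the ratio, whereas
it moves a bounding-box length ratio directly (this robustness is a
regression-tested property). For a uniform ellipse σ₁/σ₂ equals the
semi-axis ratio a/b.

**Orientation.** PCA yields an axis, not a direction. The hull boundary
is shrunk radially about the centroid (factor 0.85) so the thin
peripheral follicle ring falls outside; nuclei pixels surviving inside
are nurse-cell mass. The P-A direction points from the half (split by the
plane through the centroid normal to the major axis) with fewer interior
nuclei pixels to the half with more. Pixel counting, not cell instance
counting, keeps the rule robust to touching nuclei. An exact tie is
flagged, not guessed.

**Oocyte fraction.** The middle axis — the P-A chord through the centroid
clipped to the hull — is sampled at 30 equally spaced points from the
posterior end. For each of the 29 half-open bands between consecutive
points, the occupied fraction is interior-nuclei pixels over band pixels;
the oocyte boundary is the first band from the posterior reaching 10%.
The scan runs on the *interior-cell* mask (follicle components removed):
the epithelium wraps the posterior pole, so counting it would mark even a
DAPI-empty oocyte as occupied. Bands partition the hull exactly; the
oocyte is everything posterior of the boundary line. When no band reaches
threshold (early stages, no oocyte void) the estimate is flagged
undefined rather than forced.

**Follicle distribution and Δ.** Components lying entirely outside a
tighter shrunken boundary (factor 0.80) are follicle cells; anything
touching the interior is nurse material and is removed whole. Follicle
pixels are binned into 12 equal-angle sectors in the (P-A, normal) frame,
sector 1 opening at the anterior tip, counterclockwise. Density divides
the count by the hull-boundary arc length in the sector, measured as
polyline length on the hull polygon (less rasterization noise than
counting perimeter pixels). The uniformity score is the triangular
discrimination Δ(p, q) = Σ(pᵢ−qᵢ)²/(pᵢ+qᵢ) between the normalized
density vector and the uniform vector: symmetric, zero iff equal,
bounded by 2. This form was chosen because its range is consistent with
the empirical Δ values the score is meant to reproduce (≈0.02–0.42) and
it is isolated in one function should a different divergence be wanted.

## Detectors

**Polytene fragmentation (stage 4).** Per nurse-cell nucleus, markers are
the regional maxima of the intensity image after grayscale opening
(disk radius 2 px), discarding maxima below half the nucleus peak; a
marker-controlled watershed on the Sobel gradient splits the nucleus into
catchment basins. Basins partition the nucleus exactly. The chamber is
blob-positive when the median fragments per nucleus is ≥ 3 (config). A
smooth single-peak nucleus yields one basin by construction.

**Centripetal migration (stage 10B).** A band of total width 0.8 ×
σ_major, perpendicular to the P-A axis and centered on the detected
oocyte boundary, is wide enough to capture migrating cells but too
narrow to contain an entire nurse cell. Candidates are nuclei components
lying *entirely* inside the band; centripetal cells are candidates whose
centroid is within 0.15 × σ_minor of the hull boundary; two or more give
a 10B call. Both detectors require a cross section that actually shows
the feature; when prerequisites fail (no oocyte boundary, empty mask) the
result is flagged inapplicable rather than guessed.

## Statistical staging

Chamber growth is exponential with near-constant rate, so ln(area) is
linear in stage; OLS (statsmodels) supplies slope, R² and the pointwise
95% CI of the mean. For classification each feature *x* gets a
proportional-odds cumulative-logit model P(stage > k | x) =
logistic(βx − αₖ), fitted by maximum likelihood (statsmodels
`OrderedModel`; probit available). Stage cutoffs are αₖ/β — the feature
value where adjacent stages are equiprobable. A boundary whose adjacent
intercept gap is below 0.1 × the median gap is reported "not available":
the model cannot distinguish those stages on that feature (chamber size
fails exactly this way between stages 11 and 12, where sizes overlap).
Complete separation is detected at the data level (every adjacent stage
pair cleanly split); the fit then adds a small L2 penalty and flags the
model instead of returning a divergent slope.

`classify_stage` defaults to the size model alone — size is the most
stable feature — and optionally fuses several per-feature models by
averaging log-probabilities per stage where each feature is defined. The
end-to-end benchmark fuses size and ratio. A predicted stage 10 can be
refined to 10A/10B with the centripetal detector.

**Stage 8/9 rule.** Each group's Δ values are summarized by sample mean
and SD; the cutoff is the root of N(x; m₈, s₈) = N(x; m₉, s₉) between
the means (quadratic in x; midpoint when SDs are equal; flagged midpoint
fallback if no root lies between the means). Between the means this
threshold is exactly the likelihood-ratio rule of the two fitted
Gaussians. The accompanying two-sample t-test is Student's pooled by
default with Welch as an option.

## Synthetic data: what it emulates, what it does not

The generator renders what the pipeline consumes: an elliptical chamber
at random orientation whose log-area is linear in stage (slope 0.38 per
stage, ln 1500 μm² at stage 2, σ = 0.15 — bracketing published example
areas of ≈2200–3000 μm² at stage 5 and ≈7900 μm² at stage 8); aspect
ratio drifting 1 → 3; a near-evenly spaced follicle ring (nuclei ≈ 3.5 μm
radius, Gaussian intensity profiles so the active contour faces a real
boundary-finding task); large nurse nuclei abutting the epithelium and
the oocyte boundary; a DAPI-sparse posterior oocyte from stage 6
(fraction growing with stage and accelerating after stage 10, echoing
nurse-cell dumping); stage-4 "blobby" nurse textures; stage-10B
centripetal cells; stage-9 anterior thinning (wider spacing plus
smaller, dimmer stretched nuclei — calibrated so uniform rings score
Δ ≈ 0.00–0.03 and thinned rings Δ ≈ 0.06–0.27); background Gaussian
noise and off-chamber distractor blobs. Per-chamber magnification is
drawn adaptively (semi-major axis ≈ 90 px, 0.5–1.7 μm/px), emulating
per-object zoom; μm² features are calibration-independent. Everything is
a pure function of the spec and its seed.

It does **not** model the confocal point-spread function, shot noise,
depth attenuation, touching-chamber clutter, or biological texture inside
nuclei beyond the polytene toy model. Passing tests therefore demonstrate
correctness of the algorithms against controlled morphology, not
field performance on real micrographs; the deliberately simple noise
model means real images may need the config knobs (`otsu_scale`,
`filter_window_um`, Chan–Vese weights) retuned by visual inspection of
the audit montage.

**Feature-table generator.** For statistics tests that need no images,
feature vectors are drawn directly: LS as above; ratio 1 + 0.2·(stage−2)
+ N(0, 0.25²); oocyte fraction undefined before stage 6, then the stage
curve + N(0, 0.04²); Δ ~ N(0.12, 0.05²) through stage 8 and
N(0.30, 0.05²) after. The ratio and oocyte noise levels were chosen once
so the per-feature stage regressions give R² roughly bracketing the
anchor values the features are known for (≈0.95 size, ≈0.84 oocyte,
≈0.76 ratio); they are not fitted to any test.

## Numerical choices and edge cases

- Natural log for size (base only rescales the ordinal slope).
- Hull rasterization: pixel-center-in-polygon with 1e-9 slack; idempotent.
- Components: 8-connectivity throughout; ties to the first raster label.
- Constant images: Otsu is undefined → explicit degenerate-input error in
  binarization; Chan–Vese returns an empty mask flagged `degenerate`.
- Isotropic shapes (equal eigenvalues): axes fall back to image axes and
  the geometry is flagged.
- Oocyte bands are half-open `[Qᵢ, Qᵢ₊₁)` so they partition the hull.
- Δ terms with pᵢ + qᵢ = 0 contribute 0.
- All randomness in the synthetic layer flows from explicit seeds; the
  pipeline itself has none.

## Benchmark problem sizes

The end-to-end benchmark trains on 15 rendered chambers per stage (2–12)
and classifies an independent draw of the same size — about 330 full
pipeline runs — reaching ≥ 80% exact and ≥ 98% within-±1-stage accuracy
with the size+ratio fusion. Oracle suites use 20–50 random instances per
property and 10⁵ resamples for the permutation and Δ-bound checks. These
sizes keep the full suite at a few minutes on one CPU while leaving the
statistical assertions comfortable margins.

## Known limitations

- On chambers with strongly stretched anterior epithelium (stage ≥ 9
  morphology) the anterior rim signal weakens and the recovered hull
  reads ~5–15% low. The bias is shared by training and evaluation data,
  so staging accuracy is unaffected, but absolute late-stage areas are
  conservative. The <5% area-recovery guarantee is stated for chambers
  with an intact epithelium across the stage-2–12 size range.
- Orientation relies on nurse/oocyte asymmetry; chambers with tiny or
  absent oocytes orient arbitrarily (flagged on exact ties). Downstream
  features that depend only on the axis, not its sign, are unaffected.
- Input must be a single pre-cropped chamber; multi-chamber scenes and
  z-stack selection are out of scope.
- Stages 1 and 13 are not modeled (not separable / too variable in the
  underlying morphology definitions).
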
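# Methods

This note documents the model assumptions, the numerical conventions, the
synthetic data generator, and the design decisions taken where the
underlying methodology leaves choices open.

## Color representation

Frames are converted from 8-bit sRGB to CIE-Lab under the D65 reference
white (`skimage.color.rgb2lab`): `L ∈ [0, 100]`, `a` and `b` on the
standard signed scale, so `a > 0` reads directly as "quantity of red".
The chromatic components give an approximately illumination-invariant
description; the approximation is bounded by the cube-root compression of
the Lab transform (scaling all linear-RGB channels by 0.8 moves `a`/`b` by
at most ~1.5 units at moderate chroma, which the test suite checks at a
2-unit tolerance).

Capsule optics leave dark corners outside a circular field of view (fov).
The fov mask is estimated as the hole-filled largest connected component
of pixels whose maximum sRGB channel exceeds 10/255; masking defaults on,
because dark border pixels would otherwise dominate the negative
half-axes of the chromatic histograms. All stages ignore non-fov pixels.

## SARC thresholds

* Histograms use contiguous bins of width 1 chromatic unit covering
  `[floor(min), ceil(max)]` of the masked channel — Lab `a`/`b` derived
  from 8-bit input are near-integer, so unit bins match the data's
  resolution.
* Each half-axis sequence walks outward from zero (positive bins by
  increasing value, negative bins by increasing magnitude). Before
  differentiation the sequence is smoothed by a moving average of radius
  2 bins (configurable, 0 disables): discrete second differences of raw
  histograms are noise-dominated, and the threshold concept presumes a
  smooth curve.
* The second derivative is the central difference
  `R(k) = p(k+1) − 2p(k) + p(k−1)` over interior bins; the threshold bin
  is `argmax R`, ties broken toward the axis margin, because the sought
  feature is the outermost change in the decline rate. Half-axes with
  fewer than 3 bins or zero mass yield an ABSENT threshold and an
  all-zero component map — uniform frames are legitimate inputs, not
  errors.
* The selected bin maps back to chromatic units as its inner edge (the
  edge nearer zero) with inclusive comparison, so the bin where abnormal
  mass plausibly begins is itself retained.
* Component maps carry `|chromatic value|` rather than a binary mask:
  the subsequent non-maxima filtering and sum aggregation operate on
  images, and magnitude makes both meaningful.
* The non-maxima window is `n × n` with `n = 5` by default (odd, ≥ 3,
  clipped at borders; ties retained). The value is a package default —
  the methodology does not state one — and is exposed in configuration.

## DINOSARC scoring

A nominal even window side `s` is realized as `(s+1) × (s+1)` so the
window can be centered on a pixel; the inner window `s/2` is realized the
same way. Windows are clipped at borders and restricted to the fov mask.
The score is the Euclidean distance in the (a, b) plane between the
aggregate maximum vector and aggregate minimum vector over both windows
(since the inner window is nested, the aggregates equal the outer-window
extrema; both are still computed, keeping the definition explicit).  A
per-component distance was the main alternative; the joint chromatic
distance was chosen because the saliency notion is a change of *color*,
not of a single component. Default `s = 10`, the side found preferable in
the original tuning because it yields fewer points per image with no
missed abnormal frame.

The saliency threshold τ has no stated numeric value; the default AUTO
rule sets τ to the per-image mean candidate score, respecting the
observation that chromatic ranges — and therefore score scales — differ
per image. Ties in the descending-score ordering break row-major for
determinism.

## Regions and descriptors

SLIC runs on the Lab channels (no internal conversion) restricted to the
fov mask, with package defaults `K_sp = 200` superpixels and compactness
10 for 360 × 360 frames — a scale comparable to published superpixel
mosaics of WCE frames; both are configurable. Representative points:
a lone member represents itself; clusters reduce to the rounded
arithmetic-mean coordinate carrying the *maximum* member score (the
strongest evidence in the cluster), snapped to the nearest member when
the centroid falls outside a concave superpixel, so the representative
always lies in its region.

The 9-D descriptor order is frozen:
`[L_p, a_p, b_p, min L, max L, min a, max a, min b, max b]`.
No per-dimension standardization is applied before clustering or
classification by default (the `L` and `a`/`b` scales differ; a config
switch enables z-scoring fitted on training folds only, making the choice
auditable). The visual vocabulary is k-means (the conventional BoVW
quantizer) with 10 restarts and a fixed seed; default `K = 600` (midpoint
of the published 500–700 range), scaled down proportionally to the
descriptor pool for desk-scale synthetic runs. Assignment is hard,
nearest-word, ties to the lowest index.

## Classification harness

Stratified k-fold cross-validation (default 10 folds, fixed seed) with an
RBF-SVM. The kernel is specified by the methodology; its hyperparameters
are not, so `(C, γ)` default to a nested grid search over
`C ∈ 2^{−3..5}`, `γ ∈ 2^{−7..1}` inside each training fold (3-fold inner
CV, AUC scoring), avoiding leakage into held-out folds. Decision scores
are pooled across held-out folds; AUC is the ROC trapezoid (verified in
tests against the pairwise-concordance statistic to 1e−9);
accuracy/sensitivity/specificity are reported at decision threshold 0.
Region-level labels call a salient region positive iff its representative
point lies inside a lesion mask.

## Synthetic frame generator

The generator reproduces the statistical structure the method assumes —
not endoscopic appearance. Defaults define the study conditions:

* **Geometry.** 360 × 360 frames; fov disk of radius 0.48·side; lesions
  are soft-edged ellipses (eccentricity 0.6–1, random rotation), radius
  10 px per frame by default and drawn from U[6, 14] px at dataset level,
  deliberately including the regime below the ~460 px² mean superpixel
  area to exercise sub-superpixel localization.
* **Background chroma.** Each channel is a low-pass Gaussian random field
  mapped through the normal CDF to a *uniform* marginal over
  `[center − spread, center + spread]` (spread 5): a smooth mucosa-like
  texture whose per-image histogram is a bounded plateau with a definite
  margin, which is exactly the structure the half-axis foot-finding
  presumes. Per-image centers are drawn from U[−3, 3]² at dataset level,
  so the background range straddles zero on both axes (no spurious inner
  shoulder on a half-axis) while pooled class-conditional ranges overlap
  across frames.
* **Lesions.** The lesion channel value ramps from 0.75·offset at the rim
  to 1.0·offset in the core *beyond* the background extremum of its axis
  (offset 10 units), with a slight darkening in `L`. The planted gap of
  ≥ 7.5 units comfortably exceeds the pixel noise (σ = 1 on `a`/`b`), so
  every abnormal frame is chromatically separable within itself, pre-noise
  extrema being recorded in `truth_meta`.
* **Lightness.** Base 58 with a quadratic radial falloff of amplitude 25,
  emulating distance/angle-dependent illumination, plus mild smooth
  texture.
* **Determinism.** Every frame is a pure function of its seed; datasets
  derive per-frame seeds from a single dataset seed.

What the generator does *not* model: specular highlights, bubbles,
debris, texture detail, compression artifacts, and lesions whose color
lies inside the normal range. Consequences for interpretation: passing
recall/recovery checks shows the implementation realizes the method's
mechanics under its own assumptions, not that those assumptions hold
clinically. Notably, i.i.d. pixel noise puts isolated histogram-tail
pixels beyond the data-driven thresholds, so the detector returns a few
hundred candidate points per frame, most of them background; the
region-level descriptor classifier is nonetheless near-perfect
(AUC ≈ 1.0) because lesion regions are chromatically extreme, while the
*image-level* BoVW classifier hovers near chance in this synthetic
regime — lesion words are only ~2% of a frame's histogram mass, a far
lower signal-to-background ratio than in clinical frames where detector
points concentrate on tissue structures. The acceptance script reports
both numbers as measured.

## Problem sizes

Synthetic studies run at the native 360 × 360 frame size: 50 abnormal +
25 normal frames for detector metrics, 100 frames for threshold
recovery, and 70 abnormal + 30 normal frames (yielding ≥ 100 salient
regions per class, subsampled to 100 + 100) for the classification
studies, with the vocabulary scaled to ≤ 100 words for the ~8k-descriptor
pool. These sizes give stable statistics while keeping a full study in
the minutes range on one core.
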
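# Methods

## Scene model

The synthetic generator emulates an occlusal photograph of a dental
plaster cast. Fourteen bodies (seven per side, mirrored about the
central column) are placed along the parabola
`row = apex + q·t²` at arc-length offsets chosen so that consecutive
bodies overlap by `overlap_fraction` of the smaller footprint radius
(default 0.15; the two central incisors are adjacent across the
midline). Each body is a circular-footprint, flat-topped cap

    h(d) = H · (1 − (d/r)^p),   d < r

with height `H = 6` height units and profile power `p = 8`. The flat
top with a steep rim mimics crown morphology and is what makes the
rendered body a bright plateau bounded by a thin dark shading ring —
the regime in which intensity-based region growing is a sensible
recovery strategy for the support mask. Footprints are circular because
the detector is a circular Hough transform; tooth ellipticity is not
modelled.

Shading is Lambertian: surface normals come from central finite
differences of the height map (one-sided at borders), the grey value is
`albedo · (ambient + (1 − ambient) · max(0, n̂·ŝ))` with ambient 0.15,
body albedo 0.92 and base albedo `base_level` (default 0.55). Cast
shadows are computed by marching 1-px steps along the ray toward the
source; a shadowed pixel is attenuated by 0.35. The standard capture
set is two top lights (azimuth 90°, elevations 75° and 50°) and one
light per side (azimuths 0°/180°, elevation 35°); the light angles of
the imaging rig this emulates are free parameters, and these defaults
were chosen once to give distinct shadow patterns while keeping every
body partly lit. Noise is applied after shading in the order additive
Gaussian (σ = 0.02), shot-style additive Gaussian with intensity-
proportional variance (scale 0.01), multiplicative speckle (variance
0.02), then clipping to [0, 1]; all noise flows from a single seed, so
rendering is bit-reproducible.

The pixel scale defaults to 0.6 mm/px so the mirrored-pair distances of
the default arch span roughly 15–200 mm — the order of magnitude of
real cast measurements — at a 384×512 image size.

What the generator does **not** emulate: perspective and lens
distortion, specular highlights on wet plaster, inter-tooth texture,
gum/baseplate clutter, elliptical or rotated crowns, and contact
surfaces that are anything but the intersection of two caps. Passing
the end-to-end tests therefore shows that the chain of operations is
correct and well-calibrated for convex bodies under directional light,
not that it would reach the same scores on photographs.

## Fusion

Outside image = [left half of the left-lit capture | right half of the
right-lit capture]; central image = the converse. For odd widths the
left half takes the extra column. All four constituent images are
multiplied pixel by pixel and the product is min–max rescaled once at
the end; without rescaling, repeated sub-unity products collapse toward
zero and break fixed thresholds downstream. Contrast accumulation by
the product is a statement about *relative* variation: on the
logarithmic (Weber) scale the raw product's gradient is the sum of its
inputs' and therefore dominates each of them, which is how the
enhancement claim is tested; plain amplitude gradients near the dark
boundary shrink under min–max rescaling.

## Denoising

Wiener and median filters use symmetric reflection padding and a 3×3
default window (the smallest symmetric choice; both exposed as flags).
Where σ² ≤ ξ² the Wiener gain is clamped to zero (output = local mean);
with ξ² = 0 the filter is the identity. The median filter supports even
window pixel counts by averaging the two middle order statistics. The
pipeline applies Wiener first, median second.

## Circle detection

Votes are cast at both `p + r·∇̂` and `p − r·∇̂` because the fused image
may present bright-on-dark or dark-on-bright bodies. The gradient
threshold defaults to the 95th percentile of nonzero magnitudes, which
adapts to scene contrast. Peaks are taken from the accumulator summed
over the radius axis (robust to votes splitting across radius bins),
with greedy non-maximum suppression; ties break lexicographically by
(row, col, radius), so detection is deterministic. In the pipeline the
suppression separation defaults to 20 px and the crop-window margin to
0.35: detected radii run ~20% below the body support radius because the
strongest gradients sit on the inner edge of the shading ring, so the
window needs headroom, and at smaller separations the accumulator
double-detects large molars.

## Region growing

Growth is globally best-candidate-first with dynamic region means: the
single admissible (pixel, region) pair with the smallest
|grey − region mean| is assigned per step, with ties broken by
(difference, row, col, region id). This removes scan-order artefacts
and makes the operation exactly reproducible by a naive rescan oracle,
which the tests exploit. The lazy-heap implementation re-queues a
region's frontier whenever its mean changes; entries are stamped with a
mean version and discarded when stale, so the fast path is semantically
identical to the naive one.

The admission tolerance at the library level defaults to 0.12; the
pipeline uses 0.06 paired with a *valley completion* step. The reason
is the shading ring: a large tolerance lets the running mean slide down
the rim and leak into the base (precision collapse), while a small one
stops at the top of the rim (recall collapse). Valley completion
resolves the dilemma: after hull-merging the grown fragments, each mask
is extended by admitting unclaimed neighbouring pixels in order of
decreasing intensity, each only if it does not exceed its brightest
claimed neighbour by more than `rise_tol = 0.02` — i.e. the expansion
may only descend through the ring — and by at most 0.35 of the body
radius. It stops where intensity rises again (the base, or a
neighbouring body's flank), which is exactly the visual boundary of the
body. A grown region larger than 4× its circle's disc area is
discarded as having escaped the body.

## Merging and separation

Fragments of one body are merged by the rasterized convex hull of their
union (degenerate point sets produce the point or digital segment).
Before splitting, a mask is hole-filled, opened with a 3×3 element and
reduced to its largest connected component.

The split rests on a sign analysis of the smoothed boundary's cyclic
second derivative. With a clockwise trace in row-down coordinates the
object interior lies right of the direction of travel; the inward
normal is the tangent rotated by (t_r, t_c) → (t_c, −t_r). Along any
convex arc the second difference is *centripetal* — it points toward
the local centre of curvature, inside the object — so its inward
component is positive; at the neck between two fused convex bodies the
centre of curvature flips outside and the component turns negative.
Concave points are those below −floor, where the floor is the 25th
percentile of nonzero absolute curvatures. A run of concave points
counts as a neck corner only if its total inward turn (≈ the corner's
exterior angle) exceeds 0.35 rad; measured on rasterized shapes,
staircase dips on a convex outline total ≤ 0.18 rad while genuine
twin-disc necks exceed 0.7 rad, so the gate has a wide margin. Because
the moving average (window 9, exposed as a flag) spreads the corner's
curvature over neighbouring points, the final cut points are refined to
the narrowest crossing of the neck: within ±4 contour points of each
zone's curvature extreme, the cross-zone pair with minimal mutual
distance whose midpoint lies inside the object. On fused twin discs
this lands within ~1 px of the closed-form circle-intersection points.

The cut is the 1-px rasterized straight segment between the two points;
components are relabelled with 4-connectivity (an 8-connected digital
line blocks every 4-path), and the two largest parts are returned.
`separate_pipeline` hull-merges only when the fragment union is
disconnected: the hull of a connected two-body mask would be convex and
erase the very neck the split needs. Triple overlaps would be resolved
by re-applying the split to each part; the pipeline's scenes produce at
most pairwise contacts.

## Evaluation

Per-tooth confusion counts are taken over the full image frame, so TN
dominates and accuracy is near 1 by construction; alongside the
frame-relative FPR = FP/(FP+TN) the report carries an object-relative
FP/(FP+TP), which is the informative false-positive measure at this
frame size. Degenerate denominators yield NaN with a warning rather
than a silent 0. Mass centres are unweighted foreground centroids;
mirrored-pair distances are Euclidean distances in millimetres; percent
errors are taken against a reference distance set at full precision and
rounded only for display.

In the end-to-end run, predicted masks are assigned to truth bodies by
a Hungarian matching on centroid distance, and the reference distances
for the error report are the truth masks' own pair distances, so the
reported mean percent error measures geometric fidelity of the
segmentation, not of the generator.

## Numerical and degenerate-input choices

- Images are processed in floating point regardless of input depth.
- Odd image widths split with the extra column on the left.
- Constant products are returned unscaled by the fusion rescale.
- Empty masks, empty seed lists, non-positive radii or scales, even
  smoothing windows and out-of-range elevations raise `ValueError`
  with a named parameter; "no neck found" is a distinct
  `NoOverlapError` signal, not an error of the pipeline.
- All randomness derives from one root seed via `SeedSequence` spawns;
  identical configuration and seed give byte-identical summaries
  (stage wall times are logged, not reported).

## Problem sizes

The default scene is 384×512 px with 14 bodies; a full pipeline run
takes a few seconds on one core, and the test suite (including one
full run shared across tests and ~160 oracle/property checks) stays
within a couple of minutes. These sizes were chosen as the smallest at
which bodies, rims and shadows are resolved well enough for the
geometry to be non-trivial.

## Known limitations

- Detected radii underestimate the support radius (votes concentrate
  on the inner rim edge); downstream stages compensate via window
  margin and valley completion rather than by radius correction.
- The straight-segment cut is exact for caps/discs but would bias the
  boundary for strongly interpenetrating or non-convex bodies.
- Valley completion assumes the body rim is darker than its
  surroundings; bodies on a darker-than-rim base would need the dual
  (ascending) rule.
- The arch report requires all seven mirrored pairs; a missed tooth
  suppresses the distance table for that run (similarity metrics are
  still reported per detected tooth).
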
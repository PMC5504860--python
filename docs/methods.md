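# Methods

`myospat` quantifies myonuclear migration in two-channel time-lapse movies
of remodelled *Drosophila* abdominal muscles (DIOMs). During metamorphosis
these muscles atrophy while their nuclei migrate toward the cell centre
(anti-polar migration), then regrow while the nuclei return toward the
poles (polar migration). The pipeline detects nuclear regions, tracks
them, separates slow internal nuclei from fast sarcolyte (external)
nuclei, maps everything into a straightened medial-axis frame, and
summarizes the nuclear distribution per time point.

All physical defaults follow the reference acquisition geometry:
1.25 µm/px, 30 min/frame, images 8-bit, nuclear radius ≈ 6 px. Time is
expressed in hours after head eversion (HE) so that independently imaged
pupae can be compared on a common clock.

## Nuclear segmentation

1. **BEEPS smoothing.** The nuclear channel is denoised with a
   bi-exponential edge-preserving smoother: causal and anti-causal
   first-order recursions whose feedback gain is modulated by a Gaussian
   range kernel of the local step, combined as
   `g = (φ + ψ − (1 − λ) f) / (1 + λ)` and applied separably in x and y
   (average of the two pass orders). The *range sigma* (default 30 grey
   levels on the 8-bit scale) sets which intensity steps count as edges;
   the *spatial decay* d (default 0.1) is the per-step leak of the
   recursion, i.e. the recursion weight is λ = 1 − d. With these defaults
   a 200-grey-level edge survives within 5% while flat-field noise of
   σ = 10 loses more than half its variance — both are asserted in tests.
   Constant images are an exact fixed point.
2. **Negative LoG.** The smoothed image is convolved with −(Laplacian of
   Gaussian) at σ = 6 px, the mean nuclear radius, producing positive
   peaks at the centres of bright nuclear blobs.
3. **Saturation threshold.** The response is clipped below at zero and
   linearly rescaled so that its 99.5th percentile maps to 255; only
   pixels that saturate (map to 255) are labelled nuclear. This
   percentile anchor makes the "only saturated ridge peaks count" rule
   deterministic. A consequence worth knowing: the threshold allocates a
   fixed pixel budget (0.5% of the frame), so the apparent blob radius
   depends on how many nuclei share that budget.
4. **Components and containment.** 8-connected components smaller than
   `min_blob_px` (8) are dropped; components overlapping the muscle mask
   by less than `inside_fraction` (0.5) of their area are treated as
   outside the cell and removed. Survivors are labelled 1..K by ascending
   centroid y (ties by x), which is what makes per-frame labels
   comparable across frames for an undisturbed nucleus.

Segmented regions are *nuclear regions*, not individual nuclei: clumped
nuclei are deliberately kept as one blob, which is why the spatial
features below operate on pixel sets rather than points.

## Tracking

Whole-muscle motion is compensated before matching: frame-t blob
positions are shifted by the muscle-centroid displacement between t and
t+1 (float for centroid distances, rounded to whole pixels for pixel-set
overlaps). Matching is by mutual nearest neighbours of blob centroids,
with three outcomes per frame pair: a mutual pair continues a track; a
t+1 blob whose nearest neighbour does not reciprocate has broken off a
clump and starts a new track; a t blob whose nearest neighbour does not
reciprocate has joined a clump and its track terminates. Every blob in
every frame belongs to exactly one track; there is no gap closing across
missed detections, so occlusions fragment tracks by design. Distance ties
break toward the smaller blob label, keeping the procedure deterministic.

## Internal/external classification

Each track x with transitions i = t_s+1..t_e is scored with

    M(x) = (1/n_x) · Σ_i D_i · (1 − O_i),     n_x = t_e − t_s,

where D_i is the motion-compensated centroid displacement in px and O_i
the overlap fraction |A∩B| / min(|A|,|B|) between the consecutive pixel
sets. Tracks with M(x) strictly above λ = 7 px/transition are external.
With the default calibration, internal nuclei (0–12 µm/h) move at most
4.8 px per transition while external nuclei (25–37 µm/h) move at least
10 px, so λ = 7 sits between the two populations; the `sweep-lambda`
command reproduces the accuracy plateau around this value.

Choices where the procedure was genuinely open:

* λ is interpreted in px per transition, and n_x counts transitions, so
  M is a mean per-transition cost. A config switch (`n_is_timepoints`)
  reproduces the timepoint-count normalization instead.
* The overlap denominator is the smaller blob area so O_i ∈ [0,1] and
  (1 − O_i) stays nonnegative even across clump splits/merges.
* Zero-transition tracks (single-frame appearances produced by clump
  splitting or brief crossings) have no motion evidence and default to
  *internal*, logged as low-confidence. A transient external blob
  misclassified this way contaminates exactly one frame.

External blobs are then purged and the surviving blobs relabelled by y.

## Straightening and spatial features

Every nucleus is expressed in medial-axis coordinates: dy is the arc
length of the foot point m of its centroid on the axis, dx the
perpendicular offset signed by the side of the axis (left negative),
and α the angle between the axis tangent at m and the image y axis. The
nucleus is translated so its centroid sits at (X ± dx, dy) and rotated
about the centroid by −α; X = ceil(max muscle width) + 2 px keeps all
coordinates nonnegative. Pixel sets are transformed as float point sets
and never resampled, so per-nucleus area is preserved exactly, and for a
straight vertical muscle the transform reduces to a rigid shift.

The medial axis itself is built by skeletonizing the boundary-polygon
mask, taking the longest geodesic path through the skeleton (which
prunes side branches), fitting a smoothing spline, and by default
extending both ends along their tangents to the mask boundary so the
axis — and hence the muscle length L_c — spans pole to pole. Raw
skeletons retract by roughly half the local width at each end;
`extend_to_boundary=False` keeps the retracted axis for geometries where
that is wanted. The axis is oriented so the end with smaller y comes
first. Width samples W_c,i are chord lengths perpendicular to the local
tangent, clipped to the mask, at u equally spaced arc-length positions
(default u ≈ one sample per pixel of arc length).

Features per frame (µm where dimensional):

* **NSD** = area of the convex hull of all straightened nuclear pixels /
  muscle area. The denominator is the original mask area; straightening
  is near-isometric so this matches the straightened-cell reading while
  avoiding resampling error. Fewer than 3 non-collinear pixels → 0,
  flagged degenerate.
* **L_n** = extent (max − min) of nuclear pixel centres along the axis;
  **NM_lon** = L_n / L_c. A single-pixel nucleus has L_n = 0.
* **M_lat** = mean over arc-length bands of the nuclear width Wn_i;
  **NM_lat** = mean of Wn_i / W_c,i over the same bands. Bands are
  contiguous, height L_c/u, anchored at the axis start. Wn_i is the
  pixel-footprint extent (max − min + 1 px) of the straightened pixels in
  the band — "width of the nuclear structure", not summed coverage.
  Empty bands are excluded by default (`include_empty_bands` reproduces
  the alternative), because including them would conflate longitudinal
  clustering with lateral spread.

The two extent conventions differ deliberately: L_n measures a span
between extreme positions (centre-to-centre), while Wn_i measures the
width of a structure (its pixel footprint); each matches the worked
examples used as test oracles.

## Group statistics

Replicate feature series are snapped to a common 30-min grid of hours
after HE (nearest frame within 15 min) and compared per time point with
a two-sided Mann-Whitney U test — exact for combined n ≤ 16 without
ties, normal approximation with tie correction otherwise; all-tied
groups give p = 1. A time point is significant when −log10 p > 1.3
(p = 0.05, strict). No multiple-testing correction is applied across
time points; the number of tests is logged. Migration-phase deltas
report the change of L_n (end − start) per replicate over the anti-polar
and polar windows with a 95% t-interval; windows can be supplied
explicitly or auto-detected from a moving-median-smoothed series
(global max → min → subsequent max, with plateau boundaries taken at the
edge nearest the transition, 2% of the range counting as equal).

Detection is scored by greedy one-to-one centroid matching within a
radius (5 px default): FNR = FN/(FN+TP), FPR = FP/(FP+TP).
Classification is scored with internal as the positive class:
accuracy = (TP+TN)/(TP+FP+TN+FN).

## Synthetic fixtures

The generator renders the study conditions end to end: a capsule-shaped
muscle (round-capped tube around a straight or quarter-arc centerline,
optionally narrowing over time), internal nuclei riding the muscle on a
scripted spread program (even spacing over a fraction of the centerline
that contracts over the anti-polar window and re-expands over the polar
window, plus a small clamped random walk), external nuclei crossing the
field ballistically at 25–37 µm/h, slow sinusoidal whole-muscle drift,
moderate-contrast cross-talk blobs hugging the *outside* of the muscle
boundary, and additive Gaussian noise (Poisson optional). Everything is
deterministic given the seed.

Scene defaults are chosen for internal consistency with the
segmentation contract: 10 internal nuclei in a 512×512 frame make the
saturation budget (0.5% of the frame) match the true nucleus area, so
segmented blobs have approximately the nominal 6-px radius; the
migration program's fastest scripted step (3.3 px/frame) stays inside
the internal speed range; and nuclei keep ≥ 20 px spacing at maximal
contraction so clump events do not occur in the scripted scenes (they
are exercised separately in the tracking unit tests). The artifact
amplitude (90) is set where edge-preserving smoothing genuinely matters:
with BEEPS the artifacts stay below the saturation threshold; without it
they saturate and appear as false positives.

`scripted_feature_truth` gives closed-form feature time courses for the
straight-centerline program (ideal disks of the nominal radius, no
imaging, no jitter): L_n from the disk extents along the axis, L_c as
centerline length plus two cap radii, M_lat from per-band disk chords.
The pipeline reproduces L_n within 5% and the other features within 10%
at every frame on these scenes.

What the fixtures do **not** emulate: optics (PSF, depth attenuation),
z-projection artifacts other than the external-nucleus overlap itself,
muscle shape change beyond width scaling and drift, intensity variation
between nuclei, and true clumping during migration. Passing tests
therefore demonstrate the correctness of the algorithms under the
stated motion and intensity model, not segmentation robustness on
arbitrary real movies.

## Numerical notes and limitations

* Problem sizes in the test-suite and acceptance runs: 50-frame
  512×512 movies for end-to-end checks, 256×256 6-frame scenes for unit
  tests, 200 random frame pairs for the matching equivalence, 100 random
  tracks for the cost oracle.
* Rasterization is pixel-centre based; counts can deviate from the
  continuous polygon area by up to about half the perimeter.
* The skeleton-based axis needs a single connected, elongated mask
  (major/minor axis ratio ≥ 2); disks and fragmented masks are rejected.
* Percentile thresholding makes the segmentation relative: it always
  marks the top 0.5% of the response. Frames with no nuclei at all would
  saturate noise instead; the containment and minimum-size filters are
  the guards in that regime.
* 3D (z-resolved) analysis is out of scope; movies are 2D projections,
  which is precisely why external nuclei can overlap muscles and must be
  removed by motion rather than by geometry.
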
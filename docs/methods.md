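# Methods

This note records the model behind `rowcount`, the parameter choices that
matter, what the synthetic data does and does not emulate, and the design
decisions taken where the procedure was genuinely open.

## Imaging model and straightening warp

The system assumes a camera fixed on a vehicle, aimed at one crop row at
roughly 60° to the ground, producing 640×480 frames with 50–95%
consecutive overlap.  Under this geometry a plant's apparent lean grows
with its horizontal distance from the frame centre.  The straightening
warp maps the frame onto a symmetric trapezoid (corner shifts δx, δy);
writing a = 1 − 2δx/(W−1) and b = 1 + 2δx/(W−1) for the top and bottom
edge scale factors, the warp tilts a vertical line at column x by
4δx(x − cx)/((W−1)H) per unit height.  A scene whose plants lean by
tan(θ)·(x − cx)/cx (lean θ at the frame edge) is therefore straightened
exactly by **δx = H·tan(θ)/2**, independent of W.  The generator records
this analytic value in its ground truth and the tests verify the warp
moves plant axes toward vertical.

Warping convention: `warp_perspective(image, P)` computes
`dst(x, y) = src(P⁻¹(x, y))` with bilinear sampling and zero fill — the
standard convention in which content moves forward by P; a translation
matrix with p13 = 5 shifts the image right by 5 px.  Zero-filled border
wedges contribute nothing to the excess-green mask.  The solver
normalises p33 = 1 and maps each corner exactly (4 correspondences
determine the matrix); homogeneous scaling of P leaves the warp
unchanged.

Auto-calibration scores each (δx, δy) candidate by the sum of the n_L
largest local maxima of the projection histogram (n_L = 10 by default,
about one frame's worth of plants; fewer maxima than n_L are summed as
is).  Grid steps default to 4 px in δx and 8 px in δy, a ~40×30 grid at
640×480 that keeps the once-per-dataset calibration around a minute.
Ties break toward smaller (δx, δy) lexicographically.  Because the
excess-green index (and luma) are linear in the colour channels, the
search warps a precomputed index map instead of the full colour image —
numerically identical to warping first, about 3× faster.  The objective
rewards peak height, not plant verticality, so on synthetic scenes it is
fairly flat and can settle beyond the analytic δx; the count is
insensitive in that regime.

## Segmentation and smoothing

A pixel is vegetation iff 2G − R − B > T_g, strictly, computed in signed
arithmetic (threshold default 40).  The margin matters: with per-pixel
sensor noise of σ_n intensity levels the index noise is √6·σ_n, so soil
or residue whose mean index sits k·√6·σ_n below the threshold essentially
never crosses it.  Because the peak detector has no prominence filter
(see below), a single stray above-threshold background pixel becomes a
counted peak; the threshold's purpose is to make that event rare.

Retained pixels are scalarised to the clamped index value itself
(`intensity_mode="exg"`, vegetation density as mass; Rec. 601 luma is the
config alternative) and smoothed with a 2-D Gaussian, σ = 7 px, matched
to canopy texture and moderate foliage occlusion at the design scale of
~6 px/cm.  Borders reflect, so total mass is conserved and no artificial
edge maxima appear.  A second 1-D Gaussian (σ = 7 bins, configurable,
0 disables) smooths the projection histogram itself; both smoothing
surfaces are exposed because either alone can be insufficient: image
smoothing merges intra-canopy structure, histogram smoothing removes
residual bin noise.

## Counting

The histogram has one bin per image column; bins outside the ROI hold
zero.  A bin is a plant iff it is strictly greater than both neighbours;
the first and last bins of the histogram's domain are excluded.  Two
implementation choices close gaps the strict rule leaves open:

- **Plateaus.** Runs of equal values strictly above both flanks (common
  after quantisation) collapse to one maximum at the run centre,
  rounding down, preserving one peak per plant.
- **ROI edges as domain edges.** The peak scan treats the ROI span as
  the histogram's domain, so the ROI's own edge bins are excluded
  exactly like the image edge bins.  Without this, a plant cut by the
  ROI boundary produces a rising ramp that terminates in a spurious apex
  at the boundary bin — and in sequences that apex is re-counted every
  frame the plant straddles the boundary.

A minimum-prominence filter exists for noise studies but is off by
default: the base method counts every strict peak.

## Sequence de-duplication and the role of the ROI

With forward travel, scene content moves left: h13 ≤ 0, the previous
frame covered columns [0, W + h13), and fresh content occupies the
right-hand strip.  The buffered rule flags a peak at i as already
counted iff i + b < W + h13 (mirror-image comparison for h13 > 0), with
b = half the mean gap between neighbouring peaks (fallback W/20 for a
single peak).  The buffer widens the "new" strip by b, which embeds an
assumption: *plants are not reliably detected within b of the frame's
trailing border*.  If they were, any plant would be counted once while
inside the border band and again after moving b further in — at 90%
overlap (translation ≈ 2b) that would double-count nearly half the
entering plants.

The operator-drawn ROI is the instrument that realises the assumption.
Histogram smoothing lets a plant register while its stem is ~1.5 σ_hist
beyond the ROI edge, so the ROI's horizontal margin should be
b − 1.5·σ_hist ≈ spacing/2 − 10 px at the defaults.  That places the
measured detectability cutoff at W − b: each plant is first counted in
the frame where it leaves the buffer band, exactly once.
`synthetic.counting_roi` encodes this rule; with it, mean sequence
accuracy on synthetic rows is ≈99.7% at 60% overlap and ≈98.4% at 90%,
against a ≥96% design floor.  With a full-frame ROI the same sequences
de-duplicate to only ~73–95% — the buffer without its ROI counterpart
over-counts border plants.

Registration details: ORB keypoints (FAST detection, Harris ranking,
256-bit binary descriptors; 400 per frame by default, response threshold
exposed) matched by exact nearest-neighbour Hamming distance, with a
k-d-tree mode that is equivalent on binary vectors (squared Euclidean
equals Hamming).  Matches are kept when their distance is below
3× the minimum distance (floored at ε so perfect matches survive), then
a homography is fitted by RANSAC (seed 0, 3 px reprojection tolerance,
≤2000 trials — all configurable) and re-estimated on the inliers.  A fit
is accepted as along-row motion iff |h31|, |h32| ≤ 1e−3, |h33 − 1| ≤
1e−3 and |h11 − 1|, |h22 − 1| ≤ 0.1; otherwise (or when a pair has no
relatable features) the pair falls back to a configured nominal overlap
and processing continues.  Frames are registered pairwise only; there is
no global adjustment.

## Metrics and aggregation

Per-image error is |estimated − true| (signed errors are stored for
diagnostics); single-image accuracy is 100·(1 − mean error / mean true
count), reported to one decimal.  Sequence accuracy is
100·(1 − |total − true|/true).  Overlap error is the absolute difference
in percentage points.  Aggregating datasets: per-image statistics are
weighted by image counts; sequence accuracies (and overlap errors)
average unweighted, each row-sequence being one experiment.

## Synthetic scenes

The generator emulates: soil with brightness mottling and pebbles (the
texture keypoint detectors need), plants as a stem line plus 9–14 leaf
ellipses with leaf colours whose excess-green index is ≥105, ~10 cm
(60 px) spacing with ±3 px jitter, heights 75–100% of a 150 px default
(≤240 px ≈ 40 cm), perspective lean proportional to distance from frame
centre, multiplicative shadow rectangles (applied to plants too),
weakly green residue speckles (index drawn from [0, 18], safely below
threshold at the default σ_n = 2.5 noise), non-green background objects,
optional undersized plants (40% height), and an optional 50%-canopy
overlapped adjacent pair for occlusion studies.  Sequences render one
long row and crop integer-pixel frames, so inter-frame truth is exact
and pairs are pure translations.

Not emulated: photorealistic foliage, lens distortion, vibration blur,
exposure changes between frames, perspective *within* a sequence frame
(crops of one upright row; single-frame tilt is a shear surrogate), and
plants from adjacent rows.  Passing tests therefore demonstrate the
pipeline's logic and numerics — segmentation thresholds, peak counting,
h13 recovery, de-duplication accounting — not robustness to real
field radiometry; the registration stage in particular sees idealised,
noise-identical overlap regions, which is why synthetic h13 error
(≈0.01 px) is far below what field imagery would give.

All randomness flows from the spec's single seed through one generator;
a fixed spec renders byte-identical output.

## Problem sizes

The test suite and acceptance script use 640×480 frames throughout: 100
clean scenes and 60 cluttered scenes for single-image counting, 50
translation pairs for registration, and 20 ten-frame sequences per
overlap regime (60% with 60 px spacing → 48 distinct plants; 90% with
47 px spacing → 25), chosen to exercise the nominal study conditions at
a few minutes of total runtime.

## Known limitations

- The peak detector counts every strict maximum, so a single spurious
  above-threshold background pixel adds one plant; robustness rests
  entirely on the excess-green margin and the two smoothing stages.
- Heavily occluded neighbours (canopy overlap ≳50%) merge into one peak;
  the per-image error budget absorbs occasional ±1 errors.
- The de-duplication rule is memoryless; its correctness near frame
  borders depends on the ROI-margin convention described above.
- Overlap estimation reads only h13; rotation about the optical axis or
  scale change (terrain undulation) violates the affine-validity gate
  and drops the pair to the nominal-overlap fallback.
- Calibration transfers the first frame's (δx, δy) to the whole dataset;
  a camera knocked out of alignment mid-run invalidates it.
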
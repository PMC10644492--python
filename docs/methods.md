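# Methods

This note records the models, conventions and numerical choices behind
spykit, and what the synthetic benchmarks do and do not demonstrate.

## Imaging model and coordinate conventions

Input images are 8-bit RGB scans of flat, two-ranked grass spikes on a
dark, low-reflectance background. All geometry uses image coordinates:
origin at the top-left corner, x along columns (rightward), y along rows
(downward); angles are measured from +x toward +y in degrees in [0, 180).
Pixels are the unit of length throughout — no physical calibration is
attempted.

## Spike segmentation

Two thresholding routes produce the foreground mask:

- **Channel threshold** — strictly `channel > t` on one RGB channel
  (default red, t = 20). Red separates both green and tan spikes from a
  near-black background.
- **Scaled Otsu** — Otsu's threshold maximizes the between-class variance
  of the luminance histogram (`gray = round(0.299 R + 0.587 G + 0.114 B)`),
  scanned exhaustively over all 256 candidate levels with the smallest
  maximizer kept on ties. On dark backgrounds the background class
  dominates and pushes the Otsu level far above the darker spike tissue,
  so the mask uses `gray > f * t_otsu` with f = 0.29 by default; f = 1
  reproduces plain Otsu. A constant image yields its own value plus a
  warning.

Components are 8-connected; components below `min_area` (default 2000 px
at full resolution, scaled by the square of any image rescale factor) are
treated as debris. Spikes are numbered 1..k left-to-right by bounding-box
left edge (ties by top edge), matching how spikes are laid on a scanner.
Optional downscaling before segmentation is plain bilinear (output
dimensions `round(factor * dims)`).

Per-spike crops are padded by 10 px (zero-filled past image borders) and
converted to HSV and CIELAB (sRGB, D65). Channel scales: R, G, B, S, V in
[0, 255]; H in [0, 360); L* in [0, 100]; a*, b* signed.

Count accuracy is summarized as `rmse = sqrt(mean((pred - true)^2))`
across images, with error bars given as the population SD of the absolute
per-image error.

## Spike length

Four estimators:

- **ellipse** — full major-axis length (twice the semi-major axis) of the
  ellipse with the mask's normalized second central moments. For an
  elongated region of roughly uniform mass this estimator carries a known
  `2/sqrt(3)` (~15%) elongation bias — a uniform 300-px rectangle reads
  346 px — and it further underestimates curved spikes, which is exactly
  why the thinning estimators exist. (Regressions against manual lengths
  absorb such proportional bias, which is why ellipse fits remain popular
  for straight material.)
- **convex_hull** — the same moment rule on the filled convex hull.
- **skeleton / medial_axis** — Gaussian-blur the mask (re-binarized at
  0.5), thin to one pixel (Zhang–Suen thinning or the medial-axis
  transform), prune leaf branches shorter than `prune_px`, and take the
  longest endpoint-to-endpoint geodesic on the skeleton graph (steps cost
  1 orthogonally, sqrt(2) diagonally).

Three numerical refinements make the thinning estimators accurate against
known arc lengths:

1. **Chord resampling.** Digitized skeletons zigzag at the pixel scale
   (an even-width band's medial axis alternates between two rows), which
   inflates raw chain length by up to ~10%. The measured geodesic is
   resampled at 25-px chords (endpoints preserved) before summing, a
   standard digital arc-length correction. The raw weighted geodesic
   remains available from `skeleton_path_length`.
2. **Medial-axis corner trimming.** The medial axis runs branches into
   boundary corners at the spike tips, where its EDT radius collapses;
   end runs of the measured path whose radius stays below 0.65 of the
   path's median radius are trimmed. The Zhang–Suen skeleton retracts
   from such corners by construction and needs no trim.
3. **Seeded tie-breaking.** `skimage`'s medial axis breaks pixel-order
   ties randomly; spykit pins its RNG so batch outputs are reproducible.

`blur_sigma` and `prune_px` are *scale* parameters. The blur must reach
the scallop amplitude the spikelets impose on the outline (about the
spikelet semi-minor axis) for the skeleton to track the rachis rather
than individual spikelets, and pruning must stay well below the
tip-to-last-spikelet distance or it cuts genuine tips. The library
defaults (sigma = 2, prune = 15) suit smooth or pre-cleaned masks; the
synthetic benchmarks use sigma = 16 and prune = 30 px, matched to the
generator's default spikelet size (semi-axes 55 x 20 px). On semicircular
synthetic spikes these settings hold both thinning estimators within 5%
of the true arc length at the benchmark's fixed seed (mean ~2-2.5%);
across arbitrary seeds the medial axis occasionally posts a single spike
at 5.5-6%, because blur-induced tip shrinkage and corner-branch inflation
cannot be fully separated on scalloped outlines. The ellipse (~9-11% mean
error) and convex hull (~20-26%) always err more, reproducing the
expected accuracy ordering on curved material.

## Spikelet detection

Pipeline: pad/clean the mask, Euclidean distance transform (EDT), peak
markers, watershed.

- **Morphological cleaning** runs erosion then opening with a 3x3 cross
  kernel on a nearest-neighbor-downscaled copy of the mask, then
  upscales. Its purpose is to erase the thin rachis so spikelets separate
  into independent blobs. The parameters are again scale-bound: the paper
  of record's 10%-rescale/one-iteration recipe corresponds, at spykit's
  synthetic working scale (~half of a 600-dpi scan), to a 20% rescale
  with three erosion iterations (about a rachis half-width of erosion),
  which is what `spykit.benchmarks.RECOVERY_PARAMS` uses.
- **Markers** are the h-maxima of the EDT (prominence 1 px by default):
  an elongated blob's EDT ridge carries several near-equal local maxima,
  and h-maxima merging collapses that ripple into one candidate per blob.
  Candidates are accepted greedily by decreasing peak height (ties broken
  by position), rejecting any candidate within `min_distance` (Euclidean,
  default 25 px) of an accepted one.
- **Watershed** floods the negated EDT from the markers within the mask
  (8-connected), so the labels partition the reachable foreground
  exactly; the spikelet count is the marker count, optionally filtered by
  area bounds (default off; "auto" uses median/4 .. 4x median).
- **Ellipse fits** per label use the same second-moment machinery as the
  length module: semi-axes `2 sqrt(eigenvalue)`, orientation angle of the
  major axis in [0, 180), centroid in (row, col). Regions under 5 px are
  flagged degenerate.

On 50 synthetic spikes with 5-15 spikelets spaced >= 50 px, counting at
min_distance 25 is within one spikelet of truth for 96-100% of spikes
(RMSE 0.2-0.6). A mask that vanishes during cleaning (e.g. a bare rachis)
yields zero spikelets rather than an error at the `spikelet_segm` level.

## Shape descriptors

Geometric battery: pixel-count area, moment eccentricity and axis
lengths, extent (area / bounding-box area), solidity (area / convex-hull
area), equivalent diameter `sqrt(4 area / pi)`, max/min Feret diameters
(largest hull-vertex distance; smallest caliper width over hull edge
directions), and perimeter. Perimeter is the polygon length of the outer
marching-squares contour after one pass of cyclic three-point vertex
averaging: the raw staircase chain overestimates smooth boundaries by
~6%, the smoothed chain is within ~1% on disks and squares.

Contours are extracted after hole filling, as the longest 0.5-level
marching-squares loop, oriented counter-clockwise in the (x, y) frame as
returned (positive signed area).

Elliptical Fourier descriptors follow the Kuhl–Giardina chain
formulation: with the contour parameterized by cumulative chord length
t in [0, T], harmonic n holds the Fourier coefficients of x(t) (a_n
cosine, b_n sine) and y(t) (c_n, d_n), computed in closed form from the
polygon segments; (A0, C0) are the parameterization centroid.
Normalization rotates each harmonic by the starting-point phase of the
first harmonic, rotates spatially so the first harmonic's major axis lies
on +x, divides by the first-harmonic semi-major magnitude, and resolves
the half-turn ambiguity by sign; normalized sets are returned unchanged
(the starting-point phase is ill-conditioned when the first harmonic is
near-circular, so re-deriving it from an already-normalized set is both
pointless and unstable). Fourier power is P_n = (a_n²+b_n²+c_n²+d_n²)/2;
cumulative fractions are relative to the computed harmonic budget
(default 200), and the harmonic count for a power threshold (default
0.9999) is the smallest n whose cumulative fraction exceeds it.

One subtlety: only a circle is exactly single-harmonic under chord-length
parameterization. An eccentric ellipse leaks a small share of power
(~0.8% at axis ratio 60:25) into higher harmonics, so its harmonic count
at the extreme 0.9999 threshold is 3-5 — verified against an independent
per-segment integration oracle — while a circle's is exactly 1.

Reconstruction evaluates the truncated series; the reconstruction error
is the mean distance from reconstructed points to the original polygon
(via shapely), and is non-increasing in the harmonic count on all
fixtures. The symmetric/asymmetric split zeroes (a, d) or (b, c)
respectively; the two power sums partition the total.

## Color descriptors

All statistics are computed over the foreground-mask pixels of a spike
crop (mask membership, not literal nonzero values, defines the pixel
set). Statistics: min, max, mean, population SD, percentiles 5/25/50/75/95
(linear interpolation), CV = sd/mean (NaN at zero mean) and quartile
coefficient of variation QCV = (p75 - p25)/(p75 + p25) (NaN at zero
denominator). The canonical record is fixed at 77 fields: the seven
non-negative channels (R, G, B, H, S, V, L*) carry
{min, max, mean, sd, p5, p25, p50, p75, p95}; the signed opponent
channels a*, b* carry {mean, sd, p5, p25, p50, p75, p95}. The extended
record appends CV and QCV for all nine channels plus the full battery and
pixel fraction for each strict-sign subset of a* and b* (greenness vs
redness, blueness vs yellowness — maturity-tracking quantities).

## Latent traits and preprocessing

`pca_project` centers and scales columns (population SD; constant columns
dropped), fits a full-solver PCA, and reports both raw scores and min-max
0-1 scores per component with variance-explained fractions. The 0-1
scores are a plotting convention; distances are computed on raw scores —
mean pairwise Euclidean distances on 0-1 scores are bounded by sqrt(k)
and cannot grow as descriptor sets grow, whereas on raw scores of
standardized descriptors the total variance (and hence typical pairwise
distance) grows with the number of informative descriptors, which is the
separability effect of interest.

`feature_filter` mirrors standard pre-modeling hygiene: drop rows whose
curvature exceeds mean + 5.5 SD (when a curvature column is supplied;
spykit's suggested curvature proxy is medial-axis length / ellipse length
- 1), drop near-zero-variance columns (variance < 1e-8 or fewer than two
distinct values), then greedily drop one member of each column pair with
|Pearson r| > 0.85 (the member with the larger mean absolute correlation
to everything else), and center/scale the survivors. The operation is
idempotent.

## The synthetic scene generator

Scenes emulate 600-dpi-class scans at roughly half scale: background
10 ± 3 (8-bit, clipped), spikes whose every channel stays >= 40 so the
default red threshold 20 separates cleanly. A spike is a rachis
(centerline: straight segment or circular arc; width default 12 px,
drawn by disk dilation of the rasterized centerline) plus alternately
attached filled ellipses (default semi-axes 55 x 20 px, spacing 60 px,
attachment angle 35 degrees, centered 0.55 semi-major along the
attachment direction so each spikelet overlaps the rachis and the mask
stays 8-connected). Color runs a base-to-tip linear gradient
(green -> tan by default) with independent per-pixel Gaussian jitter
(SD 12). Ground truth records the analytic arc length, spikelet count,
arc positions and centers, and the exact footprint mask. Placement is
reject-and-resample (up to 100 tries) with a 12-px clearance; scene
rendering is deterministic in (spec, seed), with one RNG stream driving
noise, sub-seeds and placement.

What the generator does **not** emulate: awns, overlapping or touching
spikes, shadows and scanner glare, tapering rachis width, withered or
broken spikelets, and natural within-spike spikelet size gradients.
Passing benchmarks therefore demonstrates the correctness and internal
consistency of the algorithms at realistic geometry and contrast — not
field-grade accuracy on real scans, where thresholds and the minimum
peak distance must be re-tuned (the sweep tools exist for exactly that).

The three color recipes used in the separability study differ in base/tip
means (green, green-tan, tan) with per-spike mean jitter (SD 6) and
per-spike pixel-noise levels drawn from 8-16, emulating within-plot
maturity variation. On 60 spikes per replicate, the full 77-descriptor
set yields a mean pairwise PC-space distance ~9.6 versus ~2.1 for mean
RGB alone, and wins in 100% of replicates.

## Batch processing

Images are processed in sorted filename order; per-image failures are
logged and skipped. CSV output uses UTF-8, '.' decimals, a stable column
order and six significant digits; wall-clock timings go to the JSON run
log (not the CSVs) so identical configurations reproduce byte-identical
tables. The CLI exits 0 on success and 2 on validation errors.

## Problem sizes

The shipped studies use 20 scenes (1-10 spikes each) for count recovery,
20 semicircular spikes for the length ranking, 50 spikes for spikelet
recovery, 20 replicates of 60 spikes for separability, and two 2-spike
scenes for the determinism check — sizes at which every study's outcome
is stable across seeds while the whole suite completes in a few minutes
on one CPU.
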
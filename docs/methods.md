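# Methods

This note documents the models, defaults and numerical choices behind
`qdpi`, and what the synthetic benchmarks do and do not establish about real
recordings.

## Imaging model and demultiplexing

An acquisition cycle is an ordered list of light phases; a camera exposure
is taken during every `*_on` phase, so a cycle with phases
reflectance-on (10 ms) / off (1 ms) / fluorescence-on (23 ms) / off (1.5 ms)
— the default — yields two frames per cycle. A faster variant
(2 / 1 / 8 / 6 ms) is bundled as `FAST_PHASES`. Demultiplexing assigns frame
`i` to the channel of slot `i mod frames_per_cycle`; a trailing partial
cycle is dropped with a warning rather than an error because recordings
routinely stop mid-cycle. Both 8- and 16-bit stacks are supported; the
display blend `alpha·F + (1−alpha)·R` (default alpha 0.9) rounds and
saturates at the input bit depth.

Image coordinates everywhere: x = column, y = row, 0-based, origin top-left,
pixel centers at integers.

## Fluorescence quantification

**Background.** The rolling background is per-pixel and *blockwise*:
nonoverlapping windows of 1500 fluorescence frames (a short final block uses
its own frames), reduced by the per-pixel median by default. The median is
robust to a bright spot transiting a pixel for a minority of the block;
mean and minimum are selectable (`stat=`). Negative residuals are clamped to
zero since intensities are non-negative. Median subtraction is idempotent
within a block for odd block lengths. Note the implication for slow or
stationary subjects: if a spot occupies the same pixel for most of a block,
the median absorbs part of the spot; the summary statistics assume the
animal moves on the block timescale.

**Summaries and SNR.** The per-frame statistic is the maximum pixel value
(optionally restricted to a subject mask; an empty mask yields a missing
value). Sessions are summarized by the mean and the linear-interpolation
95th percentile of that trace. Two SNR forms are provided: the ratio of
mean marker-session summaries to mean control-session summaries, and the
per-frame SD over all pixels averaged across frames (an axis-marginal SD
variant was considered and rejected as the default because the all-pixel SD
is what a single number per frame most naturally means; the marginal version
is a one-liner on top of the exposed per-frame values).

**Longevity.** The control threshold is the 99th percentile of per-frame
values pooled across *all* control (vehicle/blank) sessions, matching the
single control band used for a rig. Longevity is the first imaging day whose
session summary falls strictly below that threshold; traces that never cross
are censored at the last imaged day. Longevity is antitone in the threshold.

**Spread.** The spatial autocorrelation of every 200th background-subtracted
frame is computed by FFT convolution of the frame with its point reflection
('full' mode), normalized to 1 at zero lag per frame, and averaged; all-zero
frames are skipped with a warning. No mean removal is applied — the data are
already background-subtracted and near-zero away from spots. An axis-aligned
bivariate Gaussian `A·exp(−Δx²/2σx² − Δy²/2σy²) + offset` is fitted by
`scipy.optimize.least_squares`; its SDs are the spread estimates. For a
Gaussian spot of width σ the map is Gaussian with width σ√2 — the package's
tests verify the √2 identity and linear scaling over σ ∈ {1, 2, 4} px.
Fit initialization: amplitude and center from the peak, σ from intensity
moments, offset from the minimum; σ is bounded positive. A flat map cannot
constrain the fit and is flagged degenerate (spreads left unset).

## Spot localization and keypoint refinement

Refinement replaces a tracker's prediction with the fluorescence center
within a square crop of half-width `radius` (default 10 px, clipped at
frame borders):

1. threshold the crop at `max(Otsu(crop), floor)` with `floor = 10 a.u.`
   (suppresses noise-only crops);
2. label 8-connected components and keep the one whose intensity-weighted
   centroid is nearest (L2) to the prediction, ignoring components below
   `min_component_size = 5` pixels — with a crop-local Otsu threshold,
   isolated supra-threshold noise pixels can otherwise beat the true spot on
   distance alone. Exact distance ties break by larger integrated intensity,
   then lower label;
3. estimate the center by an axis-aligned bivariate Gaussian least-squares
   fit on the component's pixels (≥ 6 pixels required for the six
   parameters; fewer, or a failed fit, falls back to the center of mass),
   or by the center of mass directly (`method="center_of_mass"`).

A refined center farther than `radius` from the prediction (possible for a
crop-corner component) leaves the keypoint unrefined and flagged, so the
distance-moved invariant holds. On symmetric noiseless spots the two
methods agree to < 1e-6 px; on noisy spots (σ 1.5–3 px, peak SNR ≥ 5) the
Gaussian-fit RMSE is below 0.25 px and degrades monotonically as SNR drops.

## QC cascade

Stages run in a fixed order: jump → PCA outliers → visibility → validity →
drop budget → pairwise distance. All thresholds live in `QCConfig`
(defaults: 30 px jump, 0.2 visibility, anchor 0.7, fluorescence 75 → 25
a.u., distance 5 → 15 px, budget 0@≤3 → 3@≥10 keypoints, 300 px pairs, 90%
PCA MSE drop). `QCConfig.knee()` anchors at 0.5 and disables PCA (two
keypoints span no useful pose space). Comparisons are strict: a 30 px step
or a 300 px pair is kept; 31 px or 301 px is excluded.

Design points that were genuinely open:

- **Jump rule.** A keypoint is flagged when *all* displacements to its
  existing neighbors exceed the limit (isolated-outlier semantics). The
  alternative — flag when *either* neighbor displacement exceeds —
  necessarily also flags the neighbors of every single-frame glitch, which
  is incompatible with zero-false-exclusion filtering; it remains available
  as `jump_rule="any_neighbor"`. Boundary frames have one neighbor and are
  flagged on that single displacement.
- **PCA outlier rule.** Pose vectors (x, y of the 10 standard nodes, only
  frames where all are present) are decomposed by SVD; `k` is the smallest
  component count whose cumulative explained variance reaches the MSE-drop
  fraction. A frame is an outlier when its reconstruction MSE exceeds
  `median + 8·1.4826·MAD` (and an absolute floor of 1e-6 so exact low-rank
  data never flags). Eight robust SDs, not three: per-frame MSE is
  chi-square-like, and a 3-MAD cut yields ~1% false positives on clean
  data, incompatible with high-precision filtering, while injected outliers
  sit orders of magnitude higher. Because one large outlier rotates the
  basis itself, the filter does one robust refinement: refit the basis on
  unflagged frames and re-score everything.
- **Budget interpolation** is linear between the anchors and floored to an
  integer (conservative). **Scores between visibility and the anchor** get
  the anchor thresholds (the scale is only defined from the anchor to 1).
- Loosening a stage's threshold never shrinks the surviving set *per
  stage*; globally, relaxing one stage can expose its violations to a later
  stage (e.g. an un-filtered jump becomes a PCA outlier), which is correct
  behavior, not a monotonicity defect.

Every excluded record/frame carries machine-readable reasons; reason counts
reconcile with set sizes, and survival is deterministic for a fixed config.

## Sample-efficiency curves

Decay form `y = a(x+1)^b + c` (error vs training frames; `c` is the error
floor) and saturating form `y = a(1 − (x+1)^(−b)) + c`. Fits use
`least_squares` with 5 multi-starts jittering the exponent around ∓0.5;
initialization `c₀ = min(y)` (decay) or `y` at the smallest `x`
(saturating), `a₀` from the left endpoint. Constant data leaves `b`
unidentifiable and is flagged degenerate. `frames_required` inverts the
decay form in closed form and rounds *up* (the returned count guarantees
the threshold); thresholds at or below the asymptote return an `UNREACHABLE`
sentinel. The pixel thresholds corresponding to 2 mm and 1 mm (4.9 and
2.45 px on the reference rig) are configuration inputs, not derived
constants, because they depend on the optical setup. Bootstrap bands
case-resample the (x, y) points (resampling unit: points, since replicate
structure is not represented), refit each resample from the full-data
estimate, and report per-x 2.5/50/97.5 percentiles; zero-noise data
collapse the band, and fixed seeds reproduce it bit-exactly.

## Multiview geometry

Cameras are pinhole models with 5-coefficient radial-tangential distortion;
world units are millimeters. Observations are undistorted to normalized
coordinates (fixed-point iteration, exact inverse to ~1e-9 for rig-scale
distortion) before the DLT: each view contributes two rows
`x·P₃−P₁, y·P₃−P₂` of the homogeneous system solved by SVD. Geometry with
all pairwise ray angles below 0.5° is flagged degenerate. Reported per view:
reprojection error (px), distance from the camera *center* (the axis-depth
variant is a one-line substitution and was not made default; the distinction
is < 1% at the rig's working geometry), and the angle between the optical
axis and the camera-to-point ray. `pixels_to_mm` is the small-angle pinhole
relation `px · pitch · distance / focal`; the Nyquist limit is twice the
one-pixel footprint (0.434 mm at 5.7 µm / 304.8 mm / 8 mm).

## Histology ratios

Otsu thresholding uses a 256-bin histogram spanning the image's value range
(16-bit data is thereby rescaled to 256 bins) and returns the center of the
best lower-class bin, so `image > threshold` is the upper class; this
matches an exhaustive between-class-variance search by construction and
agrees with `skimage` up to bin-placement convention. Enrichment pools all
ROI pixels by default (per-ROI averaging is available) and fails loudly when
the outside mean is non-positive. Colocalization sums marker *intensity*
(not pixel counts) over each Otsu mask; masks may overlap (an exclusive
mode removes the intersection); an empty/zero nucleus denominator raises.

## Synthetic benchmarks — what they emulate, and what they do not

Defaults are the study conditions: Gaussian spots with σ = 2.6 px (FWHM
≈ 6 px; the observed deposits span FWHM 6–15 px, i.e. σ ≈ 2.55–6.4),
amplitude 150 a.u. on 8-bit-scale frames over a background of 10, Gaussian
read noise SD 2 (Poisson shot noise optional), a moving bright-ellipse
subject, and exponential per-variant brightness decay across post-injection
days with phenomenological half-lives (0.8 / 2.5 / 8 / 60 days for the four
marker variants — chosen so crossing days fall in the observed ranges of
roughly 1.6, 5.3, 16.6 and > 119 days; the real decay law is unknown, only
crossing days are observed). Keypoint confidence is modeled as
`clamp(1 − error/10 px + ε)` so that confidence-scaled QC thresholds bind
in the intended direction; jitter SD is 0.5 px. The QC benchmark's pose
model spans exactly three modes (x/y translation and body scale) realized
as bounded sinusoids with seeded phases, keeping the PCA component count
stable at 3 across seeds; injected violations are constructed to trip
exactly one rule each (the pairwise violation is an in-subspace scale ramp
peaking at ~310 px; the PCA violation is a ≤ 20 px/node shear orthogonal to
the three modes). Camera rigs are five exact pinhole cameras on a 600 mm
ring. The end-to-end pipeline's scaling stage fits generator-produced curve
points (a = 40, b = −0.45, c = 2 px plus noise), since producing real
error-vs-frames points requires training external networks.

These generators validate the *estimators*: that demultiplexing, background
subtraction, localization, filtering, fitting and triangulation recover
known ground truth under controlled noise. They do not emulate fur
occlusion, skin scattering, motion blur, tracker-specific error structure
or correlated confidence miscalibration, so passing tests bound
implementation correctness, not in vivo performance.

## Problem sizes and determinism

Default test/benchmark sizes: 100-cycle recordings at 128×160 px (10,000
frames at 24×32 for the demultiplexing census), 1,000 spots for the
localization RMSE, 100-frame QC benchmarks, 50 replicates for power-law
noise recovery, 60 replicates × 199 resamples for bootstrap coverage, and
512² histology fields. Every generator consumes a single integer seed via
`numpy.random.default_rng`; identical (config, seed) pairs reproduce all
outputs bit-exactly, and the end-to-end pipeline is byte-identical across
runs at a fixed seed.

## Known limitations

- The Gaussian spot fit is axis-aligned; strongly elongated oblique
  deposits would need a rotated covariance term.
- The PCA stage assumes one animal and a fixed node set; it skips frames
  with any missing standard node rather than imputing.
- Triangulation is purely linear (no reprojection refinement by default);
  a one-step nonlinear polish can be added downstream but bundle adjustment
  of extrinsics is out of scope.
- The rolling background assumes subject motion on the block timescale (see
  above); anesthetized or stationary animals call for the `min` statistic.
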
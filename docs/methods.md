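# Methods

This note documents the models, parameters and numerical choices behind
`fieldmosaic`, and what its synthetic validation does and does not show.

## Scene and imaging model

The pipeline assumes a planar scene imaged by a projective camera, so any
two views are related by a 3×3 homography. The convention everywhere is:
homographies map source pixel coordinates (x, y) with 0-based pixel centers
into destination coordinates, normalized so element (2, 2) = 1. Crop fields
are treated as planar; terrain relief, rolling shutter and plant motion
between frames are outside the model and are known failure sources on real
data.

## Preprocessing

Lens undistortion uses the Brown–Conrady radial-tangential model (k1, k2,
k3, p1, p2 on normalized coordinates): for each undistorted output pixel,
the forward distortion model gives the sampling location in the raw frame
(bilinear). Calibration estimation is out of scope — coefficients come from
a config file, and a missing camera model passes frames through with a
logged warning. The default order is undistort → downsample because
distortion coefficients are defined for native sensor geometry; the order
is configurable. Downsampling is local-mean (area) resampling, which
preserves mean intensity; the resampling kernel choice is a documented
default since nothing in the problem pins it.

## Shot detection

The pair statistic is the cumulative-histogram L1 difference: per channel,
a 64-bin normalized intensity histogram is accumulated into a CDF and the
L1 distance between the two frames' CDFs is summed over bins and channels
(range [0, 3·(bins−1)]). Energies are split into within-shot and boundary
clusters by an *exact* 1D two-means (all sorted split points enumerated).

A fallback declares the sequence boundary-free unless both of two
scale-invariant conditions hold: the between-cluster separation exceeds 7×
the low-cluster standard deviation, and the high-cluster mean exceeds 3×
the low-cluster mean. Both matter: an exact two-means split of *unimodal*
energies always manufactures a separation of about 4 low-cluster standard
deviations (so any separation factor below ~5 fragments smooth videos),
while smooth trajectory features such as a turn can stand a few standard
deviations above very quiet within-shot energies without being viewpoint
jumps — but only a genuine jump moves the histogram by several times the
within-shot mean. Measured on the simulator, boundary-free flights reach
at most 5.8× separation and 2.8× mean ratio; flights with injected jumps
measure at least 8.7× and 4.9×.
Minimum shot length is 3 frames (shorter segments merge into the preceding
shot); a mini-mosaic of fewer frames is rarely useful, and this suppresses
boundary chatter without swallowing short genuine shots.

## Registration

Three descriptor families sit behind one interface, ordered fastest-first:

- **st** — structure-tensor block features: the per-pixel Shi–Tomasi
  response (smaller eigenvalue of the smoothed gradient outer-product
  tensor, σ = 2) is maximized within 8×8 micro-blocks; the keypoint is the
  response peak, refined to sub-pixel by a 1D quadratic fit per axis, with
  a mean/variance-normalized 17×17 patch as descriptor. Fast and accurate
  for large-overlap, translation-dominant pairs; not rotation invariant.
- **fast_local** — ORB (FAST + rotated BRIEF), rotation-robust.
- **affine_robust** — SIFT, scale/rotation invariant and partially affine
  invariant; ranked by the corner response at each keypoint since SIFT
  exposes no detector score.

Every detector returns the `max_keep` strongest keypoints (default 5000)
with a deterministic (y, x) tie-break. Matching is nearest-neighbour with a
Lowe ratio test (0.75) and cross-check, so matches are one-to-one.

RANSAC samples 4-point subsets, fits by Hartley-normalized DLT, scores by
the mean of forward and backward transfer distances against a 2 px
tolerance, rejects degenerate (collinear) samples, adapts its iteration
count to the observed inlier ratio (99.9% confidence, cap 2000), and refits
on the final consensus by least squares. All sampling derives from an
explicit seed. Two guards keep tiny spurious consensuses from being
trusted: a rung with fewer than 10 putative matches, or a consensus below
8 inliers (twice the minimal sample, which always "fits" itself), counts
as a failed rung.

The adaptive ladder accepts the first rung whose post-RANSAC inlier ratio
reaches 40%, escalating otherwise; if every rung falls short the
best-ratio result is returned flagged low-confidence rather than dropped.
The threshold is applied per pair.

**Photometric refinement.** Keypoint localization noise leaves ~0.2–0.5 px
per-pair error whose perspective component random-walks into multi-pixel
drift when a dozen transforms compose. Accepted homographies are therefore
polished by Gauss-Newton minimization of the intensity residual between
the source frame and the warped reference over their overlap (all eight
parameters; cubic-spline sampling of the reference, because bilinear
interpolation-model error is itself enough to bias the perspective terms).
This reaches ~0.02–0.1 px per pair on clean imagery. It is a local method:
it needs the feature-based initialization to be within about a pixel, and
it can be disabled per policy.

## Grouping, chaining, blending

Within a shot, frames join the open group until the group holds 40 members
(the 41st starts a new group) or the frame-center displacement under H_CR
exceeds one third of the frame width (|Δx|) or height (|Δy|) — the axis-wise
test matches the "width or height" rule; the center is used as the
displacement probe. The splitting frame becomes the new reference, and its
just-computed transform to the previous reference is taken directly as the
group's H_RR (no within-group composition). Chaining is

    H_RB(1) = I,  H_RB(g) = H_RB(g−1) · H_RR(g),
    H_CB(i) = H_RB(g(i)) · H_CR(i),

all normalized to element (2, 2) = 1. The canvas is the axis-aligned
bounding box of every frame's H_CB-warped corners (estimated in a second
pass after all chaining, so it is allocated once), with an offset shifting
base-frame coordinates to non-negative indices; canvases beyond 16384 px a
side are rejected as degenerate.

Blending is pixel filling: within a frame's warped footprint, only
still-empty canvas pixels receive values, and a provenance map records the
single source frame of every pixel. Warping is bilinear via explicit
inverse mapping with a *geometric* validity test — a sample is valid only
if it falls inside the source pixel-center extent. (Border-extending
resamplers silently clamp samples up to a pixel outside the source, which
plants a duplicated edge column in every blended strip; the explicit test
avoids that.) Re-blending a frame is a no-op, and blending order alone
determines provenance.

Meta-mosaicking registers each shot's mini-mosaic to the previous one with
the same adaptive ladder (mini-mosaics are treated as frames, their
unfilled pixels masked out of the warp), chains to the first shot's base
and blends by pixel filling. Sequential pairwise chaining was chosen over
a joint graph refinement; the stage is isolated behind `meta_mosaic` so a
graph/bundle formulation can replace it. Disjoint shots raise an error
that still carries the individual mini-mosaics.

## Quality metrics

Plain SSIM is the standard Gaussian-weighted formulation (σ = 1.5,
truncate 3.5 → effective 11×11 window, K1 = 0.01, K2 = 0.03, population
covariance, data range 255), computed on grayscale. A flat 7×7 window and
Gaussian weighting are alternative standard variants; the Gaussian form
was fixed so the implementation can be cross-checked against an
independent reference implementation to 1e−6.

SSIM_f compares the warped frame at time t with the initial (t = 1) mosaic
state; SSIM_p with the mosaic accumulated from frames 1..t−1, immediately
before frame t is blended. Both restrict to the region where frame and
mosaic are filled, eroded by the window radius so no window mixes valid
and invalid pixels; empty overlaps are recorded as missing and excluded
from means.

Scene integrity is the fraction of frames whose warped content matches the
final mosaic — measured only over mosaic pixels supplied by *other* frames.
Under pixel filling a frame trivially equals its own contribution, so
self-pixels carry no evidence; without the exclusion the statistic reads
1.0 even for randomized chains. Frames with no independent evidence (a
single-frame video) count as matched. The match threshold defaults to 0.8:
Gaussian SSIM between structurally unrelated crops of a self-similar crop
field measures ≈ 0.52–0.60 (flat soil and canopy windows are locally
indistinguishable, and the field repeats), while well-registered frames
score > 0.97, so 0.8 separates the two populations; it is configurable and
reported with the score.

## Synthetic flights

The simulator is the package's study condition, not a fixture. The field
texture is a periodic row/alley checkerboard (defaults: 48 px row period,
64 px alley period, crop occupying the middle 60%/76% of each period) with
canopy speckle at two scales — leaf-scale (Gaussian σ = 3) and plant-crown
scale (σ = 8, crowns spanning a realistic fraction of the row spacing) —
soil grain, a broad diagonal brightness gradient emulating the soil
moisture / vigor trend across a real field (which is what makes
histogram-based temporal segmentation informative: a large displacement
shifts the global intensity distribution in proportion to the distance
moved), and a light optical-PSF blur (σ = 0.8; real optics never deliver
one-pixel step edges). Everything is seeded and byte-reproducible.

Trajectories (serpentine, orbit, out-and-back, composite) solve their step
size against a polygon-clipping oracle so consecutive footprints meet the
requested IoU overlap target (default 0.9, the high-overlap regime of
video capture). Shot breaks inject an instantaneous lateral jump of at
least 1.8 frame-heights plus a 20° rotation — forcing footprint IoU below
0.1 — and rotate the downstream path with the jump so the within-shot
overlap contract is preserved exactly afterwards. Frames are rendered by
inverse bilinear warping of the texture (integer translations reproduce
crops exactly), with optional additive Gaussian noise and a multiplicative
illumination ramp, both recorded in frame metadata and off by default
(the validation baseline is noiseless).

What the simulator does *not* emulate: 3D structure and parallax,
rolling-shutter, wind-driven plant motion, specular soil, oblique-view
perspective foreshortening beyond what the planar model captures. Passing
on synthetic flights therefore demonstrates the correctness of the
geometry, chaining, blending and metric machinery under the planar
assumption — not robustness to the full difficulty of real field video.

## Problem sizes used in validation

The test suite and the acceptance script run flights of 10–200 frames at
224×160 to 320×240 px over textures of 1600×1200 to 3400×1400 px. These
sizes keep full runs to minutes on one CPU while leaving every contract
measurable: chained drift is tested on 100–200-frame flights (terminal
corner error < 2 px against exact ground truth; grouped chaining beats the
naive frame-to-frame chain), shot detection on 45-frame flights with 0–2
injected jumps across 10 seeds, and quality-metric degradation on
10-frame flights with 0–20 px of injected registration error across 20
seeds.

## Known limitations

- The planar-scene assumption is structural; real relief produces the
  pinching and bending artifacts any 2D mosaicker shows.
- Meta-mosaicking is sequential; a global refinement would distribute
  residual seam error rather than accumulating it shot by shot.
- The photometric polish assumes brightness constancy between frames;
  strong illumination drift between a frame and its reference degrades it
  (the feature-based estimate remains the fallback).
- Scene integrity depends on a configurable match threshold; the default
  is calibrated for this field-like texture class and is reported with
  every score.
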
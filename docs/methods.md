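# Methods

## Signal model and relaxometry

Every pixel's echo time course is modeled as a mono-exponential spin-echo
decay, `S(TE) = S0 · exp(−TE/T2)`, with no multi-compartment terms, no B1
inhomogeneity and no motion. The fit minimizes the sum-squared error with a
derivative-free Nelder-Mead simplex (the classic unconstrained SSE search),
initialized from a straight-line regression of log S against TE on the
positive samples. All ten echoes — the two proton-density-weighted early
echoes included — enter every fit.

Numerical choices:

* **Validity window.** Accepted fits must satisfy 0 < T2 ≤ 2000 ms and
  S0 > 0; anything else (including negative-T2 solutions that an
  unconstrained search can produce on noise) becomes an explicit
  undefined flag, never a silent zero.
* **Convergence.** Simplex `fatol` is 1e-10 relative to the initial cost,
  capped at 10,000 iterations per pixel (a safety bound; noiseless pixels
  converge in tens of iterations).
* **Noise floor.** The image border (a frame of up to 10 pixels per slice,
  which images air) provides a robust background estimate,
  median + 3·1.4826·MAD pooled over echoes. Pixels whose maximum echo
  intensity does not exceed it are flagged undefined without fitting. On a
  noiseless phantom the floor is exactly zero, so all-zero background is
  flagged and every tissue pixel is fitted.
* **Display clamp.** T2 maps are rendered with values above 120 ms mapped
  to the top color; the stored values are never clamped.

The T2 average image is the pixel-wise mean of the echoes at 45.8, 62.5 and
79.2 ms; requested echo times must match stack metadata within 1e-6 ms.
An optional display window applies only at render time.

## Volumetry

Thresholding is declarative: a `ROISpec` carries a 0-based, half-open
bounding box and a closed threshold band (both endpoints in-band; the
inclusivity choice is a convention, stated here because equality happens
with integer-valued test images, not with real data). Per ROI the largest
8-connected in-plane component is retained; ties are broken by smallest
centroid distance to the box center, then lowest label, making segmentation
bit-reproducible. There is no 3-D linking across slices, matching the
slice-wise procedure. Pixels covered by overlapping ROIs on one slice are
counted once (with a warning).

Volumes use the full-precision voxel volume
(fov_x/nx)·(fov_y/ny)·thickness = 0.0048828125 mm³ at default geometry;
`truncate_voxel_volume` reproduces the conventional 4-decimal printed
constant 0.0048 for display only. Computing with the truncated constant
would bias volumes low by 1.7%, which is why it is formatting-only; both
paths are exposed.

## Method comparison

Bland-Altman differences are map − average per session (pairing is per
session, not per slice), limits are mean ± 1.96 sample SD (n−1 divisor; the
divisor is our choice, stated because n is small in preclinical cohorts),
and the paired t-test uses t = mean/(sd/√n) with df = n−1. No normality
pre-test is run; for cohort sizes above ~30 the central limit theorem is
relied on. Zero-variance differences yield an undefined-flag t, and the
limits collapse onto the mean.

## Photometry

Net flux is ROI minus background per measurement, floored at ε = 1 p/s
(with a warning) when background exceeds signal so later log transforms
stay defined. The highest net flux of the up-to-three exposures per
timepoint is kept — total flux in p/s is already exposure-normalized, so
maxima across exposure modes are comparable. Normalization divides by the
animal's week-1 net flux; a missing week 1 is an error, never a silent
re-baseline. Missing intermediate weeks stay missing.

## Calibration

`loglog_fit` is OLS of log10(flux) on log10(volume). The regression p value
is the overall-fit F test, which for a single predictor equals the slope
t-test. Spearman ρ uses midranks for ties and is reported with its
two-sided p; perfectly concordant or discordant rankings return exactly ±1.
Non-positive volumes or fluxes are rejected with the record named — they
cannot be silently dropped without changing n. Modality pairing is by exact
(animal, week) match; unmatched sessions are excluded and counted.
Residuals follow the observed-minus-expected convention; relative residuals
divide by the observed value and are undefined (flagged) at observed zero.

## Survival

The Kaplan-Meier estimator is authored product-limit arithmetic; the median
is the *first* time S(t) ≤ 0.5 (first-crossing rule — relevant when the
curve plateaus at exactly 0.5). The plain sample median of event times is
emitted alongside as a secondary summary. Long-term survivors euthanized
symptom-free at the end of observation enter as censored records at that
day. The log-rank statistic uses the standard hypergeometric
expectation/variance tally over pooled event times (1 df, two-sided); a
group with zero events returns an undefined flag with a message.
Mann-Whitney on survival times ignores censoring — a documented limitation,
acceptable when nearly all animals reach the endpoint. For combined
n ≤ 20 the two-sided p is exact by enumerating every assignment of pooled
values to group A (midranks handle ties); larger samples use the normal
approximation with tie and continuity correction. Percent enhancement is
100·(treated − control)/control rounded to the nearest integer, halves away
from zero. No multiplicity correction is applied across arms.

## The digital phantom

The generator emulates the acquisition and biology the pipeline is meant
for:

* **Geometry.** 20×20 mm FOV in a 256×256 matrix, 20 gapless 0.8 mm
  coronal slices, TE = 12.5, 29.2, …, 162.5 ms (mean spacing 16.67 ms).
  Tests and the analysis scripts down-scale the matrix (32–64 px) and slice
  count (4–6) — the physics is per-pixel, so recovery behavior is
  unchanged while a cohort runs in seconds to minutes.
* **Tissue.** Brain ellipsoid (semi-axes 84% of the half-FOV in-plane, 90%
  through-plane), two para-midline CSF ventricle ellipsoids, one growing
  tumor. T2: brain 47 ms, tumor 68 ms, CSF 125 ms. S0 defaults (90, 100,
  120 arbitrary units) only set contrast; nothing downstream depends on
  their absolute scale.
* **Growth.** V(w) = V0·exp(k(w−1)) with V0 = 0.5 mm³ and k = ln(76)/7 ≈
  0.6187/week, anchoring V(8) = 38 mm³ — the week-8 endpoint size of the
  emulated model. The tumor occupies exactly round(V/voxel) brain voxels
  nearest its seed point (ellipsoidal metric in mm), so recorded ground
  truth is within half a voxel of the schedule and *exactly* equals voxel
  count × voxel volume.
* **Noise.** Additive Gaussian on magnitude images — the high-SNR
  approximation to Rician noise. The cohort default is SD 3 (3% of tumor
  S0), a typical MSME magnitude-image noise level; at that level the two
  contrast methods disagree only on boundary pixels, giving Bland-Altman
  differences that scatter around zero like the real cohort's.
* **BLI.** Fluxes are drawn from the power law with log10-intercept 5.81
  and slope 1.04 plus Normal(0, 0.10) log-noise, three exposures per
  timepoint with small multiplicative jitter and an added caudal background
  (~2×10⁴ p/s) that the photometry stage subtracts back out. Because the
  law is applied at week 1 too, week-8 *relative* flux in the synthetic
  cohort is ~90–120 rather than the ~245 a lower week-1 baseline
  (≈9×10⁴ p/s absolute) would imply; the baseline is exposed as a default
  in `normalize_series` examples but not imposed on the generator, whose
  job is calibration-recovery, not curve matching.
* **Survival.** Log-logistic event times with scale = the group median
  (exact by construction) and shape 8 — tight spread around the median with
  a heavy right tail resembling occasional long-term survivors. Any
  distribution with a controllable median would serve; this one is a
  documented choice, not data-derived. Censoring is administrative at day
  139 by default.

All randomness flows through explicit integer seeds; there is no global
random state, and identical config + seed reproduces every output file
byte for byte.

**What passing tests do and do not show.** The phantom has piecewise
constant tissue, no partial-volume mixing, no B1 or coil-sensitivity
variation, no motion, no luciferin pharmacokinetics and no
depth-dependent optical attenuation. Recovery of T2 values, volumes,
power-law coefficients and survival medians on this cohort validates the
*computational chain* — fitting, segmentation arithmetic, statistics — not
the biological fidelity of any real acquisition.

## Problem sizes

Unit and property tests use 32×32×4 grids; the headline phantom-recovery
computation uses 64×64×4 (≈5,000 fitted pixels, under a minute); the
analysis cohort uses 48×48×6 across 32 sessions. Full 256×256×20 sessions
are supported but take many minutes per map, matching the per-pixel simplex
procedure they reproduce.

## Known limitations

* The per-pixel simplex fit is deliberate but slow at full matrix size; a
  vectorized variable-projection fitter would be the natural next step.
* Mann-Whitney ignoring censoring biases comparisons when censoring is
  heavy.
* No ventricle/hydrocephalus exclusion logic: threshold bands are relied on
  to keep CSF out of tumor ROIs.
* The Bland-Altman analysis has no proportional-bias (regression-based)
  extension, though differences visibly grow with tumor size.
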
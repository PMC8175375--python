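# Methods

## Scope and data model

`ceusquant` quantifies bolus-kinetics from contrast-enhanced ultrasound
(CEUS) cine loops. The unit of analysis is a `CineLoop`: a stack of 2-D
8-bit frames with a caller-supplied frame rate and an optional offset
`origin_time_s` giving the time of frame 0 relative to contrast
injection. Everything downstream — time-intensity curves (TICs), peak
enhancement (PE), AUC, arrival detection, phase segmentation — operates
on this representation; any RGB or high-bit-depth input is first coerced
to 8-bit grayscale.

Conversion rules: RGB collapses with ITU-R BT.601 luma weights
(0.299, 0.587, 0.114), rounded half-up; single-channel input already in
[0, 255] passes through unchanged; single-channel input outside that
range is linearly rescaled from its own min–max onto [0, 255], with
constant input degenerating to all zeros. BT.601 is a convention, not a
claim about any scanner's internal pipeline — colorized overlays should
be avoided upstream where possible. The frame rate is never inferred
from the file: cine exports report it inconsistently (acquisition rate
and archive resampling rate can differ by a factor of two for the same
study), so both the API and the CLI require it explicitly.

Multi-page TIFF is the interchange format because it is lossless and
round-trips bit-exactly; lossy video codecs are unsuitable as canonical
storage for quantitative intensity data.

## ROI geometry

ROIs are circles, rectangles, or freehand polygons, with labels drawn
from the tissue vocabulary (artery, tumor, white_matter, grey_matter,
free-text `other:`). Coordinates are 0-based, row-major pixel indices;
a pixel's reference point is its center. Rasterization is binary
membership of pixel centers:

- circle — center distance ≤ radius;
- rectangle — the half-open block [top, top+height) × [left, left+width);
- polygon — even-odd rule, implemented as crossing-number with an
  explicit on-edge test.

Boundary pixels (distance exactly equal to the radius, centers exactly
on a polygon edge) are **included**; this tie-break is deterministic and
is what the test oracles assume. ROIs partially outside the frame are
clipped silently (tolerating small placement error); an ROI whose mask
is empty after clipping raises. Partial-pixel weighting at ROI borders
is deliberately not modelled — with typical ROI sizes the boundary
contribution to a mean is second-order, and binary masks keep the
brute-force oracle exact.

## TIC metrics

TIC intensities are mean 8-bit ROI values divided by 255, so PE lives on
[0, 1]; this makes cohort-level PE magnitudes directly comparable across
scanners that export 8-bit data and matches the "arbitrary units" scale
(≈ 0.1–0.6) conventional in 8-bit CEUS quantification.

**AUC** integrates the raw TIC over *seconds* with the trapezoid rule.
Seconds rather than frames keeps the value invariant to frame rate.
Baseline subtraction is off by default (the raw integral is the most
reproducible definition when baseline handling is unspecified) and
available as an option with integrand max(y − baseline, 0).
**Normalized AUC** divides a tissue's AUC by the same clip's artery AUC,
cancelling acquisition-duration differences; the artery's own normalized
AUC is identically 1 and is never entered into artery comparisons.

**PE tie-break:** the earliest maximal frame. On a quantized plateau
this is the only deterministic choice.

**Arrival detection** is a baseline-noise rule: baseline level and
spread are the mean and sample standard deviation of the first
`baseline_frames` samples (default 10); arrival is the first frame
starting a run of `min_consecutive` (default 3) frames above
baseline + `k_sigma` (default 4) × spread. All three constants are
exposed because the right window depends on how much pre-contrast
recording exists. With a 10-frame window the σ estimate is noisy; when
several seconds of pre-contrast baseline are available, a wider window
(e.g. 50 frames at 10 Hz) localizes a sharp onset to within ~3 frame
periods at bolus SNR ≈ 20. Clips started after the bolus (no detectable
baseline-to-signal transition) report arrival as absent; PE and AUC are
still computed and phase segmentation is skipped rather than guessed.

**Phase segmentation** partitions the clip into baseline (before the
arrival frame), wash-in (arrival to the earliest peak frame), the peak
frame, early wash-out (until intensity first falls below
baseline + `washout_fraction` × (PE − baseline), default 0.5), and late
wash-out (the remainder; empty when the curve never falls below the
cut). The half-peak split is this package's operational definition —
the five-phase vocabulary is standard but no quantitative boundary is —
and `washout_fraction` is configurable.

**Thresholding** maps gray levels ≥ upper to 255 (white) and ≤ lower
to 0; intermediate levels pass through. The white rule wins when
lower = upper. The operation is idempotent. The lower → black mapping is
a symmetric extension of the usual highlight-to-white rule.

**Motion score** is the mean absolute intensity difference between
consecutive frames in 8-bit units. A clip whose maximal score exceeds a
threshold (default 25.0) is *flagged* for review; the package never
drops data silently. The score detects probe slips and gross tissue
shifts; it cannot distinguish motion from genuine fast enhancement
changes, which is why flagging is advisory.

## Cohort statistics

Per-patient PE and normalized AUC enter a long-format table keyed by
(patient, tissue, metric). Group summaries report count, sum, mean and
*sample* (n−1) variance — the conventional choice for cohort data;
single-observation groups report variance as absent.

Comparisons are two-sided paired t-tests (implemented via
`scipy.stats.ttest_rel`; the hand formula t = mean(d)/(sd(d)/√n) with
n−1 degrees of freedom is asserted in tests): artery–brain,
artery–tumor, brain–tumor for PE; brain–tumor only for normalized AUC.
"Brain" maps to the white-matter label because white matter is the
reliably measurable low-perfusion reference, grey matter being too
small or too close to the probe to delineate in every case. Pairs with
a missing side are dropped per comparison (pairwise-complete), so
removing one patient's tumor value leaves artery–brain at full n while
tumor comparisons run on n−1. No multiple-testing adjustment is applied
(the CLI notes when several comparisons are run); with three planned
comparisons a Bonferroni factor would be 3 and is left to the reader.
Zero variance of the differences raises rather than returning a
meaningless statistic.

## Synthetic data generator

The generator exists so that the full pipeline — file formats, geometry,
TIC math, statistics — can be exercised end to end with known ground
truth.

**Curve family.** Each compartment follows a gamma-variate
indicator-dilution kernel with an additive saturating tail. With
τ = (t − onset)/time_to_peak and sharpness α:

    y(t) = baseline + amplitude · [(1 − tail)·τ^α·e^{α(1−τ)} + tail·(1 − e^{−τ})]

clipped to [0, 1]. The gamma-variate term equals 1 exactly at τ = 1 (so
with tail = 0 the maximum is baseline + amplitude at onset +
time_to_peak) and decays to zero; the tail term rises monotonically to
the plateau fraction. The sum gives a single fast peak, a biphasic
decay, and a late plateau — one curve exhibits all five phases.

**Default scene** (64 × 64, 10 Hz, 45 s, recording starting 10 s after
injection): a vertical artery band (onset 25 s after injection, 7 s to
peak, α = 3), an elliptical tumor blob (onset 26 s, 9 s to peak, α = 2)
and a white-matter patch (onset 27 s, 8 s to peak, α = 2) on a dark
background (0.02). The 1-second onset stagger and the ~7 s arterial
wash-in reflect the typical chronology of intracranial bolus passage
with a peripheral venous injection. Amplitudes are pre-divided by each
curve's maximum so rendered peaks land on the per-tissue PE means
(artery 0.584, tumor 0.436, white matter 0.175); tail levels (0.25,
0.22, 0.20) keep the blood pool brightest throughout the passage —
hence tissue/artery AUC ratios in (0, 1) — and let every curve cross
the half-peak cut before the clip ends, so all five phases are
realizable. The three regions are disjoint at default sizes, so each
emitted ROI sees exactly its compartment's curve.

**Speckle.** Noise is multiplicative and unit-mean: each pixel's clean
value is scaled by 1 + σ·(R − 1) with R a mean-normalized Rayleigh draw
and σ = `noise_sigma` (default 0.15), floored at zero, then quantized to
8 bits. A unit-mean factor leaves the expected TIC unchanged, so
parameter-recovery tests have unbiased targets (verified by Monte Carlo
on a 1-pixel ROI over 200 seeds). Intensity clipping at 1.0 and 8-bit
rounding introduce only sub-quantization bias at default levels.

**Cohorts.** `generate_cohort` draws per-patient tissue values from

    value = mean_j + sd_j · (√ρ·z_p + √(1−ρ)·ε_pj),  clipped to [0, 1]

with a patient-level latent factor z_p, so ρ (`within_patient_rho`,
default 0.8) *is* the induced cross-tissue correlation. The shared
factor models the clinically observed coupling in which a patient with
strong arterial enhancement is elevated in all ROIs; 0.8 is consistent
with the paired-difference spreads implied by cohort-level results at
n = 19. Defaults for the means and standard deviations are the
per-tissue PE values 0.584/0.436/0.175 and √variances
0.219/0.214/0.184. Clipping to [0, 1] truncates the white-matter
distribution noticeably (P(X < 0) ≈ 0.17 at mean 0.175, sd 0.184),
biasing its realized mean upward by ≈ 0.017; tests therefore compare
simulated group means against the analytic clipped-normal expectation,
not the nominal mean.

**What the generator does not emulate:** ultrasound physics (point
spread, attenuation with depth, pseudoenhancement behind strong
reflectors), probe or tissue motion, tumor heterogeneity (vital vs
necrotic regions within one ROI), recirculation bumps, or operator
variability in ROI placement. Passing tests therefore demonstrate that
the *computational* pipeline is correct and that the cohort-level
conclusions follow from the assumed effect sizes — not that the metrics
are robust to acoustic artifacts, which require compensation upstream
of this package.

## Numerical choices and degenerate inputs

- 8-bit quantization bounds every TIC sample by 0.5/255 from its model
  value; the noiseless generator/analyzer closed loop is asserted at
  1/255 per frame.
- Near its peak a gamma-variate is flat: at default artery parameters
  the curve stays within half a gray level of its maximum for ≈ 0.3 s,
  so on quantized data the earliest-maximum tie-break can sit a few
  frames before the analytic peak. Peak-time agreement to one frame
  period is therefore asserted on model-sampled (float) TICs;
  quantized-path correctness is pinned by the closed-loop bound.
- Trapezoidal AUC is exact for piecewise-linear curves, additive under
  splitting at any sample, and linear in intensity — all three are
  tested properties.
- Degenerate cases raise informative errors rather than returning
  defaults: empty ROI masks (after clipping), TICs shorter than the
  baseline window, zero artery AUC, zero-variance paired differences,
  single-frame motion scores.
- Determinism: all randomness flows through `numpy.random.default_rng`
  seeded from explicit `seed` arguments; identical seeds give
  bit-identical cines, cohorts and CLI outputs.

## Problem sizes used in validation

The standard validation runs use 64 × 64 × 450-frame scenes, 100
simulated 19-patient cohorts for the power/ordering checks, and 2000
null cohorts for type-I calibration — large enough that the binomial
uncertainty on the measured rejection rate (± ~1 % at 2000 replicates)
sits well inside the 5 % ± 2 % acceptance band, and small enough that
the whole suite runs in well under a minute.

## Known limitations

- Attenuation and pseudoenhancement are not corrected; deep or shadowed
  ROIs will bias PE and AUC downward or upward respectively.
- The motion score flags but cannot correct motion; there is no
  registration step.
- Arrival detection assumes some pre-contrast recording; clips started
  mid-wash-in degrade to PE/AUC-only summaries.
- The paired t-test assumes approximately normal within-patient
  differences; with n ≈ 19 it is tolerant but not assumption-free, and
  no nonparametric fallback is provided.
- Grey matter is carried in the label vocabulary but excluded from the
  canonical comparisons.
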
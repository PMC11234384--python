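# Methods

This note documents the models, estimators and numerical choices behind
`mcsquant`, and what its synthetic-data validation does and does not
establish.

## Coordinate and unit conventions

Arrays are indexed (y, x); punctum centroids are stored as (x, y) pairs in
nanometres, with pixel index *i* at physical coordinate *i*·pixel_size
(0-based pixel centres).  All distances, thresholds and PSF widths are in
nm so that the colocalization threshold is independent of sampling.  The
default pixel size, 77.7 nm, makes the 233 nm colocalization threshold
exactly 3 pixels, mirroring confocal acquisition near the resolution
limit; both numbers are configurable.

## Synthetic scenes

The generator emulates the *statistical* structure the analyses assume,
not image formation physics:

- **Cell mask** — an ellipse (42% of the field per axis) with a smooth
  low-order (k = 2–4) radial Fourier perturbation; always a single
  connected region.
- **Mitochondrial mask** — persistent-heading random walks (heading
  diffusion 0.3 rad/step, lengths 30–90 px) dilated to ~4 px tubule width,
  accumulated until a target fraction of the cell area is covered
  (default 0.25).  Any tubular texture with controllable area fraction
  would do; this one is cheap and deterministic.
- **Puncta** — `round(f_coloc · n_ref)` reference puncta receive a partner
  at an isotropic Gaussian offset (default σ = 50 nm, sub-resolution, so a
  true pair classifies as colocalized with probability
  1 − exp(−233²/(2·50²)) ≈ 1 − 10⁻⁴·⁸); the remaining partners are uniform
  over the cell.  `round(f_mito · n_ref)` reference puncta are constrained
  to the mitochondrial mask; the rest are placed in the cell *minus a
  2-px-dilated* mitochondrial mask.  The margin keeps ground-truth
  mitochondrial association unambiguous under the 1-px-dilated
  centroid-in-mask rule used downstream; without it, boundary-adjacent
  "non-mito" puncta would be absorbed by the dilated mask (the dilation
  ring of a 4-px tubule is roughly half the tubule area) and the f_mito
  recovery contract could not hold.  A minimum inter-punctum spacing
  (default 300 nm within each channel) is enforced by rejection sampling;
  unsatisfiable requests raise an error naming the constraint.
- **Rendering** — each point contributes a 2D Gaussian at the PSF scale
  (default σ = 80 nm, a typical confocal value for green emission at
  NA 1.4) with peak amplitude 200 (arbitrary camera units); noise is
  Poisson shot noise plus Gaussian read noise (σ = 2), then clipping at 0.
  Default puncta density is 200/channel per cell — within the plausible
  100–500 range for cultured-cell puncta; the true density in any given
  experiment varies and is a config knob, not a claim.
- **PLA fields** — nuclei are disjoint discs (radius 12 px, centres ≥ 2.5
  radii apart, mild blur); total spot count is Poisson(mean·n_cells); spot
  positions are uniform outside nuclei with a 6-px minimum spacing.  Six
  pixels (≈ 2 PSF FWHM) is the operational meaning of "non-overlapping":
  closer pairs can merge into one connected component and no
  connected-component counter can resolve them.
- **Traces** — baseline at `baseline_frac`·F_max; from the stimulus frame a
  double-exponential transient (rise τ = 3 s, decay τ = 40 s, normalized so
  the peak is exactly `peak_frac`·F_max); from `fmax_frame` a step to the
  F_max plateau, emulating pharmacological saturation of the indicator at
  the end of a recording; Gaussian noise as a fraction of F_max.  Ground
  truth ΔF/F_max = peak_frac − baseline_frac by construction.

What a green test does **not** establish: performance on real microscopy
(aberrated/asymmetric PSFs, structured background, autofluorescence,
photobleaching, out-of-focus light, segmentation bias from deconvolution),
3D colocalization, or the biological interpretation of any fraction.

## Punctum detection

Gaussian smoothing at the PSF scale → global threshold at mean + k·σ of
the smoothed image (k = 3) → components below 3 px dropped → watershed
splitting only where two local maxima are separated by ≥ 3 px (ties go to
the higher intensity, as `peak_local_max` guarantees) →
intensity-weighted centroids on the un-smoothed image.  This is a
deterministic, parameter-light analogue of plugin-based spot segmentation;
defaults are calibrated on synthetic scenes only (the detection F1 is
≥ 0.95 for SNR ≥ 10 at enforced spacing), since real acquisitions would
need their own calibration.

## Object-based colocalization and the shuffle null

NND uses a k-d tree with an explicit tie-resolution pass so that results
are bit-identical to an exhaustive all-pairs argmin (lowest partner index
wins ties).  Classification uses strict `<` at the threshold: an exact
233.0 nm separation is *not* colocalized.  The comparison is directional
and the direction is a config switch (`ref_to_partner` by default, i.e.
IP₃R→nearest-KRAP); both directions are first-class because published
descriptions of such analyses are often ambiguous about it.

The null shuffles the partner field i.i.d. uniformly over cell-mask pixels
(uniform sub-pixel jitter gives continuous coordinates), 100 iterations by
default; nuclei are not excluded from the shuffle region.  The null
statistic is the per-cell colocalized *fraction* (not raw distances), and
the 95% CI is the linearly interpolated 2.5th/97.5th percentile of the
null fractions; significance means the observed fraction falls outside
that interval.  With n_iter = 100 the CI endpoints sit near the 3rd and
98th order statistics, giving a measured type-I error of roughly 2–8% —
inside the accepted [1%, 12%] band but not exactly 5%, a known property of
percentile CIs at this resolution.  CIs are computed per cell and
aggregated afterwards.

**Chance correction.**  With a truly paired fraction *f* (pairs detected
with probability ≈ 1 at σ_offset = 50 nm) and chance probability *p* that
an unpaired reference punctum has *some* partner within the threshold, the
observed fraction is f + (1 − f)·p, so f̂ = (f_obs − p̂)/(1 − p̂) with p̂ the
null mean.  Plain subtraction f_obs − p̂ would be biased low by f·p̂ (about
0.11 at f = 0.8 with the default densities); the rescaled estimator
recovers f within ±0.05 across f ∈ {0, 0.3, 0.8}.  The analytic CSR value
1 − (1 − πr²/A)ⁿ matches the empirical null mean within Monte-Carlo error
on convex masks; on the lobed cell masks edge effects bias it slightly,
which is why the empirical null, not the formula, drives inference.

## Pixel colocalization

Manders thresholds default to per-channel Otsu within the cell mask
(deterministic and mask-aware; manual override supported).  The numerator
of each coefficient is restricted to pixels above *both* thresholds —
taking the numerator over the partner threshold alone can exceed the
denominator and leave [0, 1].  A channel with no supra-threshold signal has
an undefined coefficient and raises rather than returning 0.  The Costes
test scrambles 5-px blocks (larger than the PSF FWHM, so the null
preserves local autocorrelation) of one channel within the mask bounding
box, using only complete blocks so the scramble is an exact rearrangement
of the pixel multiset; the observed Pearson r is computed over the same
cropped region for comparability.

## PLA counting

Projection → background subtraction (mean of the darkest 5% of smoothed
pixels when no explicit extracellular ROI is given) → binarize at
mean + k·σ (k = 6) → count components with 2–100 px area.  k = 6 rather
than a more conventional 4 because zero-clipped read noise roughly halves
the measured σ, and at k = 4 an empty 256² field yields ~1–2 false
spot-pairs; at k = 6 no false spots occur in 100 noise-only fields while
true spots remain ≥ 4× above threshold.  At higher densities merged spot
pairs undercount in proportion to the collision probability of the
spacing model — a documented limitation of any binarize-and-count
procedure.  The unit of analysis is the field (spots/nuclei); fields with
no detected nuclei raise and are excluded with a logged reason, never
reported as 0/0.  Condition comparisons operate on per-field values.

## Calcium quantification

F_max is the mean of the top decile of frames within the designated
saturation window — robust to single-frame outliers, unlike a raw max.
The window is validated: if the trace maximum *outside* the window exceeds
the plateau estimate by more than 5%, the window cannot contain the
saturated signal and is rejected.  Baseline is the mean over the
pre-stimulus window.  The peak is the max of the response segment after a
3-frame centred moving average (confined to the segment so the F_max step
cannot leak in): a single-frame max is biased upward by ~σ_noise·√(2 ln N)
(≈ +0.04 at 5% noise for small responses), while windows much longer than
the ~3 s rise time clip the true peak.  Pooled over ΔF/F_max ∈
{0.1, 0.3, 0.5} at 1–5% noise the estimator's bias is ≈ 0.001 and RMSE
≈ 0.02; per-amplitude bias reaches ±0.016 (positive for small responses,
negative for sharp large ones).  ΔF/F_max is dimensionless and exactly
invariant to rescaling the raw trace.  A linearity flag marks responses
whose peak exceeds 50% of F_max, outside the regime where indicator
fluorescence tracks [Ca²⁺] approximately linearly; no conversion to
absolute [Ca²⁺] is attempted.  No bleaching/drift correction is applied; a
drift diagnostic flags baselines with relative slope above 0.01 s⁻¹.

## Statistics

Two-tailed classical (equal-variance) Student's t-tests by default, Welch
optional; one-way ANOVA with Tukey's HSD for >2 groups; repeated-measures
one-way ANOVA (statsmodels `AnovaRM`, complete blocks required) with
Bonferroni-adjusted paired t-tests for matched designs.  α = 0.05.
Identical-group degenerate cases (zero-variance differences) report p = 1
rather than NaN.  Type-I error of the two-group test is calibrated to
[3%, 7%] over 2000 null simulations in the test suite.

## Reproducibility

A single global seed fans out to per-stage seeds via
`SeedSequence([seed, stream, index])` (counter-based), so any stage can be
rerun in isolation; all derived seeds are < 2³¹.  Reports embed the config
hash (SHA-256 of canonical YAML), the seed and the package version, and
identical seeds give byte-identical CSV/JSON reports.  Plot output (PNG)
is off by default and excluded from the byte-identity contract.

## Known limitations

- 2D only: no 3D segmentation, distances or deconvolution.
- The chance-correction estimator assumes near-certain detection of true
  pairs; for offsets approaching the threshold it underestimates f.
- Connected-component PLA counting undercounts at densities where spots
  overlap; nuclei closer than ~1 diameter merge in DAPI counting.
- The CSR formula ignores edge effects and is a cross-check, not the null.
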
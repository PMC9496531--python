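# Methods

This note documents the models, parameter choices and numerical conventions
behind `liqspec`, and what its synthetic tests do and do not demonstrate
about real instrument data.

## Spectral model and conventions

A spectrum is a single absorbance trace on a strictly monotone wavenumber
grid. Instrument exports may be stored high-to-low; internally every grid is
ascending, so all interval bounds are unambiguous `(low, high)` closed
intervals. Absorbance is treated as linear in analyte amount at fixed path
(Beer–Lambert); consequently no normalization is ever applied to spectra —
the whole analysis is quantitative.

## Anchored global baseline

Instrument software re-zeroes each spectrum against the blank using two
signal-free anchor windows, 2031–1865 and 3971–3799 cm⁻¹. The vendor
algorithm is not published, so `liqspec` defines the correction as
subtracting the straight line through the per-window centroids (mean
wavenumber, mean absorbance of each window). With the standard two windows
the line interpolates both centroids exactly, which gives the operation its
defining property: the corrected spectrum has zero mean absorbance in each
anchor window (to 1e-9, limited only by floating point). A least-squares
line through *all* anchor points individually would not have this property
(per-window residual means are generally nonzero for a two-cluster fit),
which is why the centroid form was chosen. With a single window the line is
the ordinary least-squares fit within that window; with three or more, a
least-squares fit through the centroids. The correction is idempotent and
commutes with uniform scaling. Whether the vendor baseline is linear or a
spline through the anchors is unknown; linear is the minimal model
consistent with two anchor windows.

Atmospheric compensation, smoothing and ATR penetration-depth correction are
deliberately out of scope.

## Region AUC and the local-baseline caveat

Quantification integrates the baseline-corrected trace over a named region
with the composite trapezoid rule. Region bounds snap to the grid points
inside the closed interval — at 8 cm⁻¹ sampling the worst-case bias is under
half a bin, and it cancels between calibration and samples because both use
the same grid. Defaults: CH = 2800–3000 cm⁻¹ (recommended), C=O =
1710–1760 cm⁻¹; extended variants reach 3010 cm⁻¹ (alkene CH of unsaturated
lipids) and 1700 cm⁻¹ (free fatty-acid carboxyl).

The optional *local baseline* subtracts the chord area
`(h_low + h_high)/2 · (high − low)` computed from the snapped endpoint
heights, i.e. the result is the signed area between the trace and the chord
joining its endpoints. (A published description of this step prints the
endpoint *difference* rather than the sum; that form is zero for symmetric
peaks and cannot represent a positive baseline correction, so the chord
interpretation is used and documented here.) Local subtraction makes the AUC
invariant to any added straight line — and therefore blind to broad
underlying bands only in appearance: when a broad OH/NH hump lifts a
region's endpoints, the chord bisects the lipid peak and the quantity is
biased. The default pipeline therefore does **not** apply it, and the test
suite checks the divergence pattern: chord-subtracted and plain CH AUCs
agree within ~2% on pure-lipid model spectra but differ by >30% once a
broad OH contaminant is present.

## Calibration and ICH figures of merit

Calibration is ordinary least squares of AUC on mass (or log₂AUC on
log₂mass). Blank (mass 0) replicates are excluded from the regression and
provide `sd_blank`, the SD (ddof = 1) of blank AUCs over the target region;
at least three blanks are required unless `sd_blank` is supplied. Figures of
merit follow the ICH convention:

* LOD = 3·sd_blank/slope, LOQ = 10·sd_blank/slope — always on the linear
  scale; for a log–log curve the linear-scale slope comes from an auxiliary
  OLS on the raw points (the log-slope has the wrong units for this
  formula). LOQ/LOD = 10/3 holds exactly by construction.
* SNR = (mean AUC at the lowest non-zero standard − mean blank AUC) /
  sd_blank. Published curve characterisations report single SNR values
  without a formula; this definition is explicit and configurable.

Quantification inverts the curve: `mass = (AUC − intercept)/slope`. Signals
below the intercept yield non-positive masses that are reported as computed
and flagged below-LOD — never clipped. Flags use strict inequality, so a
mass exactly at the LOD is *not* below-LOD (but is below-LOQ).

## LiQ score and classification

`LiQ = h(2922) / [h(2888) + h(1645) + h(1034)]` on peak heights linearly
interpolated at the nominal wavenumbers and clamped at zero (post-baseline
noise can dip negative; a negative denominator term is meaningless).
Interpolation rather than local-maximum search keeps the score deterministic
at 8 cm⁻¹ resolution; a ±8 cm⁻¹ local-max mode exists behind a flag for
samples with shifted bands. Technical replicates are averaged before
scoring; the replicate CV of the score is available from the unaveraged set.

Classification thresholds (all configurable): score ≥ 1.7 → `pure_lipid`
(boundary inclusive; the recommendation is "over 1.7" without stating
inclusivity, so the inclusive convention is documented here); score ≤ 0.3514
(the pure-metabolite level) → `low_quality`; 0.3514 < score ≤ 0.7 →
`monophasic_extract` (butanol:methanol extracts run near 0.5, plasma
monophasic extracts roughly 0.26–0.68); otherwise `indeterminate`. A
degenerate denominator (all three reference peaks zero) yields +inf with
classification `pure_lipid` and a warning.

The three `peak_ratio` presets (2922/2888, 2922/1645, 2922/1034) are
reconstructions assembled from the catalogued band wavenumbers for
characterising detergent, protein and sugar contamination individually; no
decision thresholds ship with them.

## Synthetic spectrum generator

Each analyte is a set of Gaussian bands (center, sigma, relative amplitude)
plus a scalar response (AU per µg); a spectrum is the amount-weighted sum of
band profiles, optional drift line, and seeded additive white Gaussian noise
on an 8 cm⁻¹ grid from 4000 to 656 cm⁻¹ (419 points). Gaussian shape keeps
every oracle in closed form (heights analytically, region integrals via
erf); the linearity, ratio and screening properties under test are
shape-independent. Noise is white on absorbance — the simplest model
consistent with a blank-SD-based detection limit.

Band amplitudes are free parameters of the fixture library, calibrated once
and frozen:

* the lipid models score LiQ ≈ 1.81 (inside the 1.7–2.0 pure band) with a
  pronounced CH_min trough (0.52 of CH_max);
* the detergent model's CH_min/CH_max proportion (≈1.0) exceeds the lipid's
  (≈0.55);
* protein carries amide I/II, sugar the 1034/1160 C–O bands, RNA
  amide + phosphate bands, metabolite a sugar+amide blend with weak CH;
* the metabolite model scores LiQ ≈ 0.29–0.30. This is deliberately below
  the 0.3514 cut-off rather than equal to it: in a linear mixture model the
  score of lipid+metabolite blends approaches the pure-metabolite score
  from above, so a metabolite model sitting exactly at the cut-off could
  never be flagged when mixed with any lipid. Placing it at ≈0.30 preserves
  the qualitative separation (pure ≫ 1.7 vs metabolite ≪ cut-off) while
  making cut-off screening of mixtures well-posed;
* the default noise SD of 0.006 AU puts the closed-form CH-region LOD of
  the lipid model at ≈12 ng — the sensitivity regime of a well-performing
  ATR instrument (any single fitted LOD scatters around this with the
  blank-SD estimate, roughly ±25% at nine blanks).

All band models are silent (<2×10⁻³ AU per response unit) inside both
baseline anchor windows, so drift-free renders sit on the blank baseline and
are flagged baseline-corrected at creation.

The default titration design is 3 blanks plus 40, 125, 250, 500, 1000 and
3000 ng in triplicate (27 spectra), matching the quantitative range of the
method. The screening cohort generator renders 107 samples (three technical
replicates each) of lipid (0.3–1.5 µg) plus metabolite load expressed as the
ratio of metabolite to lipid band response: clean samples draw ratios 1–4
(LiQ ≈ 0.42–0.68, the monophasic-extract band), the 25 planted low-quality
samples ratios 15–30 (LiQ ≈ 0.31–0.34, below the cut-off with a margin far
exceeding the noise-induced score scatter). Synthetic MS total intensities
track the true lipid amount with 8% lognormal measurement error and are
scaled to the MS measured fraction. Because the contaminant inflates the CH
region but not the MS total, including flagged samples degrades the
FTIR-vs-MS correlation and excluding them restores it — the directional
behaviour the screening step exists to produce.

### What the simulations do not capture

Real ATR spectra have Voigt-like band shapes, correlated (1/f and
atmospheric) noise, penetration-depth wavelength dependence, solvent
evaporation artifacts, and contaminant spectra far richer than a few
Gaussians. Passing the synthetic suites demonstrates that the *algorithms*
are correct (integration, fitting, thresholds, plumbing) and that the
workflow's qualitative claims (local-baseline bias, score separation,
screening benefit) follow from band structure alone — not that any
particular real instrument will achieve a 12 ng LOD or a given correlation
with MS.

## Problem sizes and determinism

Default analyses are deliberately small: 419-point grids, 27-spectrum
calibrations, 321-spectrum cohorts, 500-fit coverage sweeps — the full test
suite runs in seconds. Every stochastic step takes an explicit seed;
per-spectrum streams derive from (seed, index) sequence seeding, so any run
is bit-reproducible and independent across spectra.

## Known limitations

* Single-analyte (total lipid) quantification only; no per-class analysis or
  spectral deconvolution.
* The chord interpretation of the local-baseline formula is a documented
  choice, not a vendor specification.
* The LiQ thresholds are instrument- and workflow-calibrated constants;
  users with different optics or extraction chemistry should re-derive them
  from their own pure-lipid and metabolite references (all thresholds are
  configurable).
* JCAMP-DX and proprietary binary formats are not read; only two-column CSV.
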
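# Methods

`ligaquant` analyses two kinds of measurements made on histological
sections of knee collateral ligaments — FTIR microspectroscopic images
(bio-composition) and quantitative polarized light microscopy (qPLM)
orientation images (collagen microstructure) — and compares outcomes
between experimental groups with linear mixed-effects models.  Because
studies of this kind rarely deposit raw images, the package ships a
phantom generator that emulates the statistical structure of both
modalities with known ground truth, so every stage is validated by
parameter recovery rather than by comparison to withheld data.

## 1. Spectral forward model

A spectrum is a sum of area-normalised band profiles on a polynomial
baseline:

    A(nu) = sum_b  a_b * g_b(nu; c_b, w_b)  +  P(nu)

with `a_b` the integrated area (a.u. cm^-1), `c_b` the band position
(cm^-1) and `w_b` the FWHM.  Profiles are Gaussian by default; a
pseudo-Voigt (eta-weighted Gaussian/Lorentzian mix of equal width) is
available because real amide bands carry Lorentzian character — the
recovery suite uses Gaussians so closed-form areas exist.  The default
band set mimics a collagenous ligament: amide I (1658), amide II
(1546), CH2 bands (1450, 2919), amide-III-region bands (1334, 1234),
amide B (3077), and a six-component carbohydrate/GAG family
(1031–1161) whose summed area over 1000–1184 cm^-1 tracks proteoglycan
content.  The acquisition axis is 715–4000 cm^-1 at 4 cm^-1 spacing,
pixel pitch 6.5 µm.

### Why the default widths look oddly specific

The analysis chain smooths with a second-order Savitzky–Golay filter of
21 samples (an 84 cm^-1 footprint) and integrates each band above a
chord (straight line between the window endpoints).  The SG kernel has
negative side lobes at ±36–40 cm^-1; when a band's smoothed tail —
including those lobes — reaches a window endpoint, the chord picks it
up and the windowed AUC shifts by up to tens of percent.  Band mass
within ~44 cm^-1 of an endpoint structurally cannot pass this
estimator.  The default FWHMs (35.0, 38.8, 35.8, 51.1, 22.4, 34.2,
13.6 for the single bands; 18 for the carbohydrate components) were
therefore calibrated once, on the noiseless default spectrum, so that
the chain is area-transparent per band (|bias| < 0.05% single-band,
within ±2.3% end-to-end across groups after scatter correction).  The
integration windows for the 1450 and 1334 bands are set to 1406–1494
and 1290–1378 cm^-1 — wide enough to clear the kernel footprint while
still bracketing only their own band; the carbohydrate-region limits
(1000–1184) are fixed by convention, which is why its two edge
components (1031, 1161) carry small default weights.  All widths,
limits and weights are configuration, not constraints.

## 2. FTIR pre-processing

Order: tissue mask → denoise → scatter correction → quality filter.

* **Tissue mask** — Otsu threshold on the per-pixel mean absorbance
  (a fixed threshold may be supplied).  Flat images yield an empty mask
  with a warning.
* **Denoising** — Savitzky–Golay, order 2, window 21 samples; edges by
  evaluating the polynomial fitted to the terminal window.  The filter
  reproduces quadratics exactly and is linear.
* **ME-EMSC scatter correction** — the interferent subspace is built
  from van de Hulst extinction curves

      Q_ext(rho) = 2 − (4/rho) sin rho + (4/rho^2)(1 − cos rho),
      rho = 4 pi d (n − 1) nu,

  evaluated on a 10×10 grid of refractive index n ∈ 1.1–1.4 and sphere
  diameter d ∈ 2–7.1 µm (the published defaults of the algorithm
  family), compressed by SVD to the smallest basis explaining 99.99% of
  the curve-set variance.  Each pixel is fitted by weighted least
  squares (uniform weight on 1000–4000 cm^-1) as

      A = a + b nu + c m(nu) + sum_i g_i q_i(nu),

  and corrected as `(A − a − b nu − sum g_i q_i)/c`.  The corrected
  spectrum replaces the reference and the loop repeats until the RMS
  change between successive corrected spectra falls below 0.05 a.u. or
  45 iterations are reached.  Two consequences of this formulation are
  worth knowing:

  1. With a reference-independent curve family the subspace never
     changes between iterations, and once the reference has been
     replaced by the pixel's own corrected spectrum the raw spectrum
     lies exactly in the design span — iteration 2 is a fixed point
     whenever c > 0.  Convergence in 1–2 iterations is therefore the
     norm, and the iteration cap is a guard, not the usual exit.
  2. The **quality RMSE** reported per pixel is the residual of the
     *first* fit, against the configured reference: later residuals
     are ~1e-15 for every pixel and carry no information.  Pixels with
     first-fit RMSE above the cap (default 0.05 a.u.) or with c ≤ 0
     are removed from the mask.

  The default reference is the package's own collagen-like spectrum
  (no measured reference ships with the package); any reference can be
  loaded from CSV.  Because EMSC normalises each pixel to the
  reference amplitude, absolute AUC scales are relative to that
  reference — which is also true of the measured values this package
  is designed to emulate.

* **In the orchestrated pipeline** the reference is passed through the
  same SG filter as the data, so the fit compares like with like.

## 3. Band quantification

Per band: extract the samples inside [lo, hi], subtract the chord
through the endpoint values (endpoints become exactly zero), integrate
by the trapezoid rule.  Chemical images apply this per pixel (NaN on
background); the per-sample outcome is the mean over tissue pixels
surviving the quality filter.  The 2919 cm^-1 band is computed and
reported but has no associated group truth.

## 4. qPLM crimp morphometry

Azimuth images hold the slow-axis angle (degrees, modulo 180), i.e. the
local collagen fiber direction.  Orientation analysis folds
`|azimuth − axis|` into [0°, 90°] (0 parallel, 90 perpendicular to the
ligament long axis) and averages.  Crimp analysis:

1. **ROI selection** — candidates on a grid with stride equal to the
   ROI size (default five 50 × 500 px strips), ranked by mean
   retardance with a deterministic row-major tie-break; ROIs whose
   low-retardance fraction exceeds 20% are flagged out-of-plane and
   excluded.  Without a retardance channel all ROIs count as in-plane.
2. **Profile** — per column, the signed deviation of azimuth from the
   longitudinal axis averaged across rows, then a 5-px moving average.
3. **Centring** — the profile is centred by the midrange of its 10th
   and 90th percentiles.  This absorbs constant fiber tilt like a mean
   would, but is immune to the duty-cycle bias a plain mean picks up
   when the ROI spans a non-integer number of crimp periods (a plain
   mean shifted the limb angles by up to 5% in testing).
4. **Limbs and valleys** — sign runs of the centred profile are the
   ascending/descending limbs (runs shorter than 3 px merged into
   neighbours); `phi_up`/`phi_down` are means of |angle| over limb
   interiors, trimming 5 px at each limb end so smoothing ramps around
   the zero crossings do not bias the means.  Valleys are
   descending-to-ascending zero crossings, localized by linear
   interpolation (sub-pixel).
5. **Summary** — crimp angle `theta = (phi_up + phi_down)/2`, crimp
   length = mean valley-to-valley distance, averaged over accepted
   ROIs.  A sample with zero accepted ROIs is flagged excluded.

On noiseless triangular phantoms the recovery is exact (theta within
0.5°, length within one pixel) across theta ∈ {5°, 15°, 25°} and
length ∈ {50, 100, 200} µm; estimates are invariant to uniform tilt
and scale linearly with pixel size.

## 5. Phantom generators

**FTIR** — background pixels carry Gaussian noise only; tissue pixels
(default centred ellipse on a 64 × 64 grid; the instrument-scale raster
is available by configuration) carry the group spectrum times a
per-pixel lognormal jitter (5% relative sd, mean 1), then a forward
Mie distortion `(1 − w)·A + w·s·Q_ext` (defaults n 1.3, d 5 µm,
w 0.3), then i.i.d. noise (0.005 a.u.).  Ground truth records the
configured per-band areas, mask and jitter field.  Identical spec and
seed give bit-identical cubes.

**qPLM** — azimuth(x, y) = tilt + wave(x) with a triangular fiber wave
(square-wave angle signal alternating ±theta, period = crimp length;
sinusoidal variant available), plus wrapped Gaussian orientation noise
(2° default).  Retardance is high except in a low-retardance block of
rows covering the configured out-of-plane fraction.  The stored mean
fiber angle is computed from the noiseless field, so it is exact for
any tilt/theta combination.

**Study-level variation** — the orchestrated study (39 ligaments: 6
operated animals contributing destabilised and contralateral knees,
one lateral ligament lost to histology, plus 4 control animals)
additionally draws biological variance: per-band compositional factors
(animal-level sd 2%, sample-level sd 3%, lognormal) for FTIR and
multiplicative crimp factors (animal 10%, sample 15%) for qPLM.
Because the scatter correction normalises every pixel to the reference
amplitude, a global per-sample scale (section thickness) would be
removed by design; compositional factors are therefore renormalised to
unit EMSC-visible amplitude per sample.  A corollary — as in real
normalised spectroscopy — is that a band with no configured group
effect can still show small relative group differences when other
bands shift (closure), so strict nulls hold only marginally.

**What the phantoms do not emulate:** spatial texture (fascicle
boundaries, insertion-site gradients), resonant Mie dispersion,
instrument drift, section-quality artifacts, and 3-D (out-of-plane)
fiber angles.  Passing recovery tests therefore demonstrates the
correctness of the estimators under the assumed noise model, not
robustness to every artifact of real tissue.

## 6. Group comparison

Outcomes are compared with REML linear mixed models (statsmodels
MixedLM engine): fixed effects ligament + group (FTIR; no interaction
by default) or ligament × group (qPLM), random intercept per animal,
optionally a knee-within-animal component (FTIR default).  qPLM
outcomes are natural-log transformed.  Estimated marginal means are
model predictions on the factor grid, averaging unlisted factors with
equal weights; under the log transform they are reported on both
scales.  Pairwise group contrasts within each ligament use
t statistics with **Satterthwaite degrees of freedom** computed from
the REML profile likelihood (delta method on the contrast variance
with a finite-difference Hessian over the variance components —
validated against lmerTest/emmeans to four decimals) and a Tukey
(studentized range) familywise adjustment (Bonferroni/Holm/none
configurable).  Boundary fits (a variance component at zero) are
returned as valid fits; a contrast whose standard error is undefined
at the boundary carries NaN p-values rather than failing.

Power at this design is intrinsically modest: a 1-residual-sd
destabilised-vs-control effect is a partly between-animal contrast
carried by ~10 animals, and the full procedure detects it in roughly
45% of simulations unadjusted (≈35% Tukey-adjusted) — the same rates
as the reference R implementation on identical data.  The test suite
asserts sanity bounds (≥35%/≥20%) rather than an unachievable higher
figure, alongside a familywise type-I error ≤6% at nominal 5% over
1000 null simulations.

## 7. Numerical and engineering choices

* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; pipeline stages derive per-sample seeds
  from the base seed, and reruns are byte-identical.
* Band windows on the 4 cm^-1 grid are realised as the samples inside
  [lo, hi]; limits off the grid snap inward by at most one sample.
* The EMSC design matrix uses a [0, 1]-scaled wavenumber column for
  conditioning; a rank-deficient design raises rather than returning
  garbage.
* Degenerate inputs: flat cubes yield empty masks with warnings; empty
  masks yield NaN outcomes; crimp profiles with a single sign or fewer
  than two valleys reject the ROI with a diagnostic; an
  all-out-of-plane sample is flagged excluded.
* Desk-scale problem sizes are the defaults (64 × 64 cubes, 640 × 640
  orientation images); the instrument-scale sizes are reachable purely
  through configuration.

## 8. Known limitations

* Absolute AUC values are relative to the reference spectrum's
  amplitude; only a matching reference makes scales comparable across
  datasets.
* The non-resonant extinction model omits the complex refractive index
  (no resonant Mie correction) and attenuated-total-reflectance
  effects.
* Limb angles are pooled per ROI, not per crimp period (identical for
  ideal waves; slightly different for amplitude-modulated crimp).
* With ~10 animals, variance components are estimated with wide error
  (median recovery within 50% over 200 simulations) and boundary fits
  are common; fixed-effect contrasts are the reliable output.
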
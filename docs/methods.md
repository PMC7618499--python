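# Methods

This note documents the statistical models, numerical choices and
limitations behind each analysis in `mpmqc`, and what the synthetic
generators do and do not emulate.

## Photon transfer analysis (`mpmqc.photon_transfer`)

**Model.** The detector is assumed linear: a pixel receiving an expected
photon count λ per frame is digitized as `I = q·λ + I₀` with sensitivity
`q` (grayscale levels/photon) and zero level `I₀` (grayscale). Under
Poisson photon statistics the frame-to-frame variance is
`V = q²λ = q·(I − I₀)` — linear in the mean with slope `q`.

**Paired-frame variance.** Variance is estimated from adjacent-frame
differences, not from the full time series: for frames X and X′ (one-frame
delay), `M = round(½X + ½X′)` and `D = ½(X′ − X)²`. Any signal that is
approximately constant across one frame period (calcium transients
relative to typical frame rates, slow drift, bleaching) cancels in the
difference, isolating quantum noise. Rounding of M is half-up so pair
means stay on the integer grayscale grid. A four-pixel border margin is
excluded by default because scan-mirror turnarounds and laser blanking
corrupt edge statistics.

**The fit.** The PTC `(I, C, V)` is fit by a count-weighted Huber
regression (`sklearn.linear_model.HuberRegressor`, transition at 1.35
robust-scale units, ≤100 iterations, tol 1e-6). Robustness matters because
bright image regions carry genuine dynamic signal: their variance exceeds
the Poisson prediction quadratically, and a plain weighted least squares
would inflate the slope. Numerical detail: intensities, variances and
weights are standardized before the Huber call and the coefficients mapped
back — the joint (coefficient, scale) Huber optimization converges to a
degenerate near-zero-scale solution when V spans many orders of magnitude
on its raw scale. Levels with fewer than 100 samples are excluded from the
fit (kept in the PTC) since their variance estimates are too noisy for the
robust loss; levels within 1% of a stated saturation level are excluded
because clipping suppresses variance. A non-positive slope marks the fit
invalid (flag, not exception): a static scene with pure read noise
legitimately produces one.

**Diagnostics and units.** The CoV image is the per-pixel ratio of the
observed paired-difference variance to the Poisson prediction
`q·(mean − I₀)`: 1.0 where quantum noise dominates, >1 under activity or
instability, <1 where the acquisition applies reduced gain (scan-speed
compensation near the frame edges) or where clipping bites. Note the
convention: this is variance over predicted variance, which is the
quantity that equals 1.0 for a Poisson process (one source protocol
describes it verbally as mean over variance, which would not have that
property; we implement the quantity matching the stated interpretation).
Photon-flux conversion divides: `X̂ = (X − I₀)/q`, so one detected photon
maps to one unit (the displayed formula in the source protocol multiplies
by q, but its own worked example — "(400 − zero level)/sensitivity = 3
photons" — divides; we treat the multiplication as a typographical
inversion). Negative flux values are retained: clipping them would bias
ROI sums upward. ROI rates are `y = (γ/dt)·Σ hᵢX̂ᵢ` with γ = 1 for uniform
unit weights; the "optimal" normalization `γ = ΣhX̄ / Σh²X̄` and the
"simple" `γ = Σh / Σh²` coincide on uniform images. Their ordering on
nonuniform images follows the sign of the weight–brightness correlation
(pairwise decomposition of the γ difference); both are provided.

## PMT benchmarking (`mpmqc.pmt`)

Statistics are computed on the middle frame of each series by default
(start/stop frames can carry shutter artifacts); a whole-series option
exists. The black point is the mean of the zero-gain dark frame and is
subtracted from all subsequent statistics. SNR is
`(µ_light − µ_dark)/σ_dark`; a zero dark SD yields NaN, never infinity.
ROC–AUC is computed by the Mann–Whitney rank identity with midrank ties —
the probability a random light pixel exceeds a random dark pixel — and is
therefore invariant under monotone transforms of the pixel values. Anode
current is `µ_pixel·(ADC_V/ADC_levels)·TIA_gain` using the *raw* light
mean (offset current flows too). The gain recommendation takes the
smallest gain on the AUC plateau (≥99.5% of the sweep maximum,
configurable) subject to HV ≤ 80% of the tube maximum and an anode-current
limit; if the plateau is unreachable within those limits the best
admissible gain is returned instead, and only a fully inadmissible sweep
yields "no recommendation" with the binding constraint named. Tritium
reference sources decay as `k = exp(−d/17.75)` (d in years); trend
analysis divides historical light means by k so only excess decline is
attributed to the detector.

## PSF metrology (`mpmqc.psf`)

Bead profiles along x, y and z are extracted through the
intensity-weighted 3D centroid with 3-pixel transverse averaging (the
extraction width is our choice; line profiles are standard but their width
rarely stated) and fit with `A·exp(−(s−s₀)²/2σ²) + B` via
`scipy.optimize.curve_fit`, moment-based initial values. FWHM = 2√(2 ln 2)·σ,
converted with the *calibrated* pixel pitch, never stage-nominal values.
Fitting B instead of pre-subtracting background makes FWHMs invariant to
offset and amplitude scaling. Stacks with >0.1% voxels at the saturation
level are refused (a clipped apex biases widths low). A tilt warning fires
when the lateral centroid drifts >1 pixel across one axial FWHM; no
automatic rotation is applied (an optional pre-rotation hook can be built
on the returned centroids). The axial correction factor for
refractive-index mismatch is `√(4n₂² − NA²)/√(4n₁² − NA²)` (n₁ immersion,
n₂ sample), applied multiplicatively to axial distances; it tends to n₂/n₁
as NA→0. Aggregate (cluster) beads are identified from kernel-density
modes (Silverman bandwidth) of integrated intensities: the first mode is
the single-bead unit, candidates within ±25% are singles, others labeled
by their rounded multiple.

## FOV geometry and homogeneity (`mpmqc.fov`)

**Pixel pitch.** The grid period in pixels is detected from the first
significant peak of the overlap-normalized (unbiased) autocorrelation of
the row/column mean profiles — the biased estimator's triangular taper
pulls interpolated peaks inward by ~0.3% at typical period counts — and
then refined by regressing sub-pixel (parabolic) dark-line minima
positions on line index, whose slope is the period with error shrinking in
the number of visible lines. Grids rotated beyond ±5° are refused with
advice to rotate the physical target (resampling would alias the period).

**Distortion.** Each grid line is traced perpendicular to its axis by
windowed sub-pixel minima (rows on crossing lines are skipped — the
minimum is undefined there), fit with a straight line, and the maximum
perpendicular residual reported as % of the FOV extent. Lines bowing
toward the field center at midline indicate pincushion, away indicate
barrel; the sign vote is weighted by off-center distance since central
lines carry no sign information. Affine transformations introduce no bow,
so the metric isolates radial distortion.

**Homogeneity.** Frame-averaged flat-field images are normalized to their
maximum (99.9th percentile with a warning when the maximum is an isolated
hot pixel >2% above it), profiled through the center horizontally,
vertically and along both diagonals (bilinear sampling at unit arc
spacing), and summarized by edge ratios and the displacement of the
top-decile-brightness centroid from the geometric center (flagged beyond
5 px as possible misalignment). Comparisons against stored references
require matching zoom and geometry and report the per-profile maximum
absolute difference.

## Pulses and power (`mpmqc.pulse_power`)

Enhancement factor `g = gp/(τ·f_rep)^(n−1)` with gp = 0.59 for sech pulses
(this value reproduces the conventional "~50,000" for 150 fs / 80 MHz
two-photon operation); duty cycles ≥1 are refused. Transform-limited
bandwidth uses τ·Δν ≥ 0.3148 (sech) and the first-order conversion
Δλ = λ₀²Δν/c with c = 299,792,458 m/s. The GDD optimum is the grid argmax
of mean intensity — only tested settings are selectable — with a parabolic
apex refinement reported when three points bracket the peak; a boundary
maximum is flagged as insufficient compensation range. The pre-sweep
stability check requires ≥120 s of recording and fails beyond a 10%
start-to-end change (tolerance exposed; the 30% mid-sweep stop rule is
likewise a configurable threshold). Power tables interpolate with a
shape-preserving monotone PCHIP; since an electro-optic modulator's
transmission is sin²-shaped, the maximum can occur before 100% modulation
and the inverse lookup is restricted to the ascending branch below the
detected maximum. Drift checks compare maximum power and matched
modulation rows, failing beyond 5% (default), and refuse comparisons
across wavelength, objective or beam mode.

## Synthetic generators (`mpmqc.fixtures`)

The generators sample exactly the models above with known parameters:
Poisson photon counts through a linear gain with rounding, optional read
noise, bit-depth clipping (a flag disables clipping for oracle tests,
since saturation deliberately distorts the PTC); 3D Gaussian beads with
optional axial shear; Gaussian-profile grid lines with the radial warp
`r′ = r(1 + k·r²)`; radially-profiled flat fields; gain-parameterized
dark/light PMT frame pairs with zero amplification forced at zero gain.
All accept a seed and are bit-reproducible.

They do **not** emulate: diffraction or scattering optics, calcium
indicator kinetics (activity is a multiplicative low-rank time course),
detector nonlinearity, afterpulsing, temperature-dependent dark current,
or motion. Passing recovery tests therefore demonstrates correctness of
the estimators under their stated assumptions, not robustness to every
real-world artifact; the CoV image and the robust fit are the designed
defenses against the most common departures (activity, saturation, gain
compensation).

**Study conditions.** Sensitivity recovery uses 500-frame 128×128 movies,
per-pixel photon rates uniform in [0.5, 10] (a typical in-vivo calcium
imaging regime of a few photons per pixel per frame), sensitivities 20,
96.9 and 678.7 grayscale/photon (the latter two matching published
instrument regimes), zero level 100, read noise 2 grayscale. The nonzero
read noise is part of the realistic detector model: an exactly noise-free
simulated chain at high q exhibits a rounding artifact with no physical
counterpart, in which pair means of equal photon counts fall exactly on
.5 boundaries and split intensity clusters into a zero-variance level and
an inflated neighbor. Bead stacks use 0.3 µm z-steps, 0.1 µm pixels,
FWHMs (0.5, 0.5, 2.0) µm and peak SNR 10. Grid images use 100 µm pitch
(and the 25 µm electron-microscopy grid variant). The acceptance script
uses 5 seeds per recovery (medians) to stay fast; the test suite uses 20
for the sensitivity criterion.

## Known limitations

- The photon sensitivity is a single global estimate; systems with
  position-dependent gain (resonant-scan dwell-time compensation) are
  *detected* by the CoV image but not locally corrected.
- The PTC method assumes frame-to-frame-uncorrelated quantum noise;
  temporal filtering or motion correction applied before analysis biases
  the estimate, so raw movies must be used.
- PSF fits assume a single isolated bead; the aggregate detector flags
  clusters but the fitter does not deblend them.
- Distortion tracing requires grid lines spanning ≥80% of the FOV and
  fails on heavily vignetted grid images.
- The rig log performs threshold flagging only; no change-point detection.
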
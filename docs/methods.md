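# Methods

This note documents the models, numerical conventions and design choices
behind `crystalsight`, and what the synthetic validation does and does
not demonstrate.

## Feature extraction

All features are computed in double precision on the raw 0–255 intensity
scale (no [0, 1] rescaling), so magnitudes stay interpretable — e.g. the
HELM background of a clear solution sits at ≈ 1.00. Conventions, chosen
once and applied uniformly so that every operator is testable against a
brute-force oracle:

- **Boundary handling**: replicate ("nearest") padding for every
  neighborhood operation (local mean/variance, range, Gaussian,
  Sobel/Prewitt/Laplacian). Brenner's spacing-2 differences are the one
  exception: they are evaluated on the valid (unpadded) support only,
  because replicate padding would zero the boundary differences and bias
  the mean.
- **Means, not sums**, for the focus measures (BREN, TENG), making values
  independent of image resolution; variances are population variances
  throughout (single-frame statistics, n is large).
- **HELM** is the mean of r = max(I, μ_k)/min(I, μ_k) with numerator and
  denominator floored at one gray level, which keeps r finite and ≥ 1
  when zero-intensity pixels occur and gives exactly 1 on any uniform
  frame.
- **Wavelet features** use the orthogonal periodized Daubechies-6
  transform, so detail + approximation energy equals total image energy
  exactly; WAVR = E_detail/E_approx is therefore a proper energy ratio.
- **Histogram features** use the native 256-bin 8-bit histogram;
  percentiles interpolate linearly. `HistSumBK`/`HistTailBK` are pixel
  *fractions* below/above the P5/P95 cuts of a designated background
  frame; without a background reference they fall back to the frame's own
  percentiles and the extractor flags the self-reference.

### The 80-feature catalog

Only part of the catalog is pinned down by the framework's documented
constraints; the registry here is a reconstruction that preserves the framework's structure
exactly: 80 features = 6 global + 15 histogram + 59 transform, produced
by 31 distinct methods, including every feature the analyses refer to by
name (IntM, IntV, IntIdxD, HistSpan, HistSumBK, HELM_5, BREN, PRWV, TENG,
LAPV, GLLV_5, RngM_7, RngM_71, RngGaussV_157, WAVR). The 59 transform
features combine a kernel ladder k ∈ {5, 7, 15, 31, 71, 157} for the
range / local-variance / HELM families with gradient, wavelet,
range-of-Gaussian, Gaussian-gradient and difference-of-Gaussian methods.
The generated JSON manifest records the full mapping; structural counts
are asserted at registry construction.

## Signal conditioning

The Hampel filter replaces sample i by its window median when
|x_i − med| > n_σ · 1.4826 · MAD (the standard robust formulation of a
"local standard deviation"); zero deviation is never an outlier, so
constant series pass through despite MAD = 0. The order-1
Savitzky–Golay smoother reduces to the centered window mean. Both filters
shrink their windows symmetrically at the series ends instead of padding:
no data are fabricated exactly where clear/cloud events sit. The
aggressive optimized Hampel setting (n_σ = 0.1, window 29) effectively
acts as a running median and is appropriate only for very low-noise
feature channels such as HELM_5.

Peak resolution is Res = |Δμ|/(2(σ_n + σ_{n+1})). This form was adopted
because Res = 1 makes the two μ ± 2σ envelopes touch, at which point the
optimal single threshold classifies Φ(2) ≈ 97.7% ≥ 95% of draws
correctly. Degenerate inputs: equal means with zero SDs → 0; distinct
means with zero SDs → +∞. Level statistics for resolution ladders use
sample SDs (ddof = 1) on raw values; binned ladders (k_av = 5) bin within
each level before computing moments.

## Event detection

The background model takes the per-feature **median** (robust to stray
frames) and **SD** over 15 clear-solution frames, auto-selected from the
hold at the maximum temperature; σ_bk is computed on raw, unconditioned
values so the band reflects the measurement noise the detector actually
faces. Cloud = first run of ≥ 3 consecutive conditioned samples outside
m_bk ± n_Nuc σ_bk (the persistence rule suppresses single-sample
glitches that survive the Hampel filter); clear = first sample of the
final inside-band run, provided it is ≥ 3 samples long and reaches the
series end ("complete dissolution" is terminal within a heating
segment). The event temperature is read from the frame log, not
interpolated. σ_bk = 0 yields a zero-width band in which any deviation
triggers; this is documented behavior, not an error.

Filter optimization is an exhaustive grid search (k_Hpl × n_σ × k_SG)
minimizing the mean squared detected-vs-true temperature error over all
annotated events and all three band levels n_Nuc ∈ {4, 8, 16};
undetected events are penalized with the segment's squared temperature
span, and ties resolve to the smallest (k_Hpl, k_SG). Small smoothing
windows win on low-noise synthetic signals because every extra
half-window of smoothing delays threshold crossings by the same number
of frames.

## PLSR

SIMPLS (PLS1): factors are extracted directly from the covariance vector
s = Xᵀy; scores are normalized, X-loadings are deflated from s via a
Gram–Schmidt-orthonormalized loading basis — the numerically stable
formulation. Inputs are mean-centered only (no unit-variance scaling), so
weights remain interpretable on raw feature scales. With ncomp =
rank(X), predictions coincide with OLS; for univariate y the truncated
fits also coincide with NIPALS PLS1, which the tests use as an
independent cross-check. Rank-deficient extraction stops early and
records the achieved component count; a zero covariance vector yields the
constant-mean model.

Cross-validation is seeded K-fold (observation-level) or group K-fold
(whole experiments as fold units, shuffled by seed); MSECV ties resolve
to the smallest ncomp (parsimony). Q² uses the *training* mean in the
denominator — the conservative convention; the alternative (test-mean)
was rejected because it can reward constant predictions on shifted test
sets. The 85:15 split is realized as round(0.85 n) training
observations.

## Van't Hoff modelling

ln x = −ΔH_d/(R T) + ΔS_d/R is fitted by unweighted OLS of ln x on 1/T
(kelvin internally, °C at the interfaces). R²_adj and the RMSE of ln x
are reported; a two-point fit is exact with undefined R²_adj. The mixed
solvent is treated as two species (diglyme + water) in the mole-fraction
conversion. Molar masses (solute 241.29, diglyme 134.17, water
18.015 g/mol) and the solvent density (0.95 g/mL, optionally a callable
of temperature) are external literature constants supplied through
configuration — they are not outputs of this package, and mg/mL figures
inherit their uncertainty.

## The synthetic experiment generator

The generator emulates what the analysis assumes about backlit
suspension imagery, nothing more:

- **Rendering**: bright background (level 200) with a radial vignette
  (8% corner fall-off), additive Gaussian noise, and N dark filled
  ellipses (aspect ratio U(0.3, 1), random orientation, gray level
  25–55% of background, darkest-wins overlap). N ~ Poisson(λ) with
  λ = x_c · V_frame / m̄, where V_frame is the imaged volume (pixel area ×
  100 μm optical depth) and m̄ the mean particle mass from the lognormal
  diameter distribution (median 30 μm, shape 0.4, crystal density
  1.25 g/cm³). The noise default (SD 0.1 gray levels) is sub-quantization:
  backlit imaging with strong illumination is quantization-limited, which
  is what a clear-solution HELM background of 1.00 within 10⁻³ (observed
  1.0006 ± 2·10⁻⁶ at the 480 × 640 reference geometry) implies.
- **Kinetics**: a single first-order relaxation of x_c toward the
  solubility-implied equilibrium (dissolution 2 min⁻¹, growth
  0.5 min⁻¹ — dissolution of small crystals at high undersaturation is
  fast), with nucleation during cooling triggered at supersaturation
  S = 1.5 (≈ 10–18 K metastable zone width for these enthalpies).
  Population balances, habit, polymorphism and hydrodynamics are out of
  scope; only the x_c trajectory matters downstream.
- **Transmission**: T = 100 exp(−k_ext x_c) with k_ext calibrated so T
  remains above 99.9% for all x_c below the blind-spot density
  (default 5 mg/mL, threshold crossed 1% beyond it) — reproducing the
  fixed-threshold probe's early/late detection failure mode.
- **Reproducibility**: one master seed; each frame draws from a
  counter-derived substream, so any frame is bit-reproducible in
  isolation and whole experiments are byte-identical across runs.

What passing the synthetic suite shows: the pipeline recovers events and
densities correctly when the data match the model's assumptions
(homogeneous suspension, density-proportional particle counts, stable
illumination). What it does not show: robustness to real-world
set-to-set variability — changing particle habit, fouling, bubbles,
illumination drift — which is precisely why across-set transfer degrades
on real data in ways the generator cannot reproduce.

## Study designs and problem sizes

- **Detection cohort**: 12 metastable-zone-width experiments over three
  solvent ratios (loadings spanning 0.014–0.150 g solute per g solvent), each a
  30-min background hold above saturation, −0.5 K/min cooling through
  nucleation, +0.5 K/min re-heating through dissolution; 480 × 640 frames
  at 0.05 fps (the slow end of the supported 0.05–0.5 fps range, chosen
  to keep the cohort a few hundred frames per run). Filter optimization
  trains on one experiment per solvent ratio, mirroring the three
  training-set practice of optimizing on a small annotated subset;
  detection uses n_Nuc = 4.
- **Calibration runs**: stepwise heating (5 K steps, 30-min holds,
  1 K/min ramps) from below to above saturation; PLSR observations are
  the last 25–40 frames of each hold (≥ 5 min after the step, mirroring
  equilibration practice), binned with k_av = 5. These use a reduced
  192 × 256 geometry: feature–density relations are resolution-dependent
  only through the particle count per frame, and this size keeps the
  full-registry extraction of the 12-run scenario within a couple of
  minutes while preserving ≈ 30 particles per frame at the highest
  densities.

## Known limitations

- The feature catalog beyond the named features is a reconstruction;
  rankings of individual reconstructed features carry no authority.
- The renderer's particle model (opaque ellipses, no blur or diffraction)
  makes texture features *more* regular than real crystal imagery;
  absolute Res values on synthetic ladders are optimistic.
- mg/mL quantities depend on the configured solvent density; only g/g
  quantities are density-free.
- Detection assumes one clear and one cloud event per ramp segment;
  oiling-out or polymorph transformations are not modelled or detected.
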
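# crystalsight

Direct image-feature analysis for small-scale crystallization process
characterization.

Small-scale crystallization experiments (1–8 mL vials with a backlit
camera and a transmissivity probe) are the workhorse of early-stage
process development: they yield solubility curves, metastable zone widths
and rough kinetics from milligrams of material. The classical automated
readout — a fixed transmission threshold — is blind to low crystal
suspension densities, so it reports *clear* points (complete dissolution)
too early and *cloud* points (nucleation onset) too late, and those errors
propagate straight into the fitted solubility model.

`crystalsight` implements the alternative: extract a vector of **80 image
features** from every raw grayscale frame — no object detection or
segmentation — and use those features for

1. **clear/cloud point detection** via a background-referenced divergence
   criterion on a single robust feature signal, and
2. **crystal suspension density prediction** (mg crystals per mL solvent)
   via SIMPLS partial least-squares regression.

Because no reference image datasets ship with this problem, the package
includes a first-class synthetic experiment generator (dark elliptical
crystals on a bright vignetted background, Poisson particle statistics,
first-order dissolution/growth kinetics, a van't Hoff solubility truth
and a transmission channel with a configurable blind spot) so that every
stage is testable end-to-end against known ground truth.

## The method

**Features.** Three families, 31 extraction methods, 80 features per
frame: global intensity statistics (n = 6: mean `IntM`, variance `IntV`,
index of dispersion `IntIdxD`, skewness, kurtosis, histogram entropy);
a parametrization of the 256-bin intensity histogram (n = 15, including
`HistSpan` and the background-referenced tail masses `HistSumBK` /
`HistTailBK`); and local-neighborhood transforms (n = 59): Brenner
(`BREN`), Tenengrad (`TENG`), Prewitt/Sobel/Laplacian statistics, the
Helmli–Scherer mean-ratio focus measure `HELM_k`, range filters
`RngM_k`/`RngV_k`, local-variance filters `GLLV_k`/`GLVN_k` (kernel
ladder k ∈ {5, 7, 15, 31, 71, 157}), range-of-Gaussian features
(`RngGaussV_157`), Gaussian-gradient and difference-of-Gaussian
statistics, and two-level Daubechies-6 wavelet detail energies (`WAVR`).

**Peak resolution.** A feature's ability to separate two adjacent
suspension-density levels with measured means μₙ, μₙ₊₁ and standard
deviations σₙ, σₙ₊₁ (normality assumed) is ranked by

    Res = |μₙ₊₁ − μₙ| / (2 (σₙ + σₙ₊₁))

Res = 1 corresponds to the μ ± 2σ envelopes touching; at that point ≥ 95%
of samples are correctly classified by the optimal single threshold
(analytically Φ(2) ≈ 97.7%).

**Detection.** Per experiment, a background model (median `m_bk` and SD
`σ_bk` of each feature over 15 clear-solution frames at the hottest hold)
defines a band `m_bk ± n_Nuc σ_bk`. After Hampel outlier removal and
order-1 Savitzky–Golay smoothing, the *cloud* point is the first
sustained divergence of the feature signal (default `HELM_5`) outside the
band; the *clear* point is the first sustained, terminal convergence back
into it. Filter windows (`k_Hpl`, `n_Hpl,σ`, `k_SG`) are grid-optimized
against annotated ground truth by minimizing the temperature MSE over
band levels n_Nuc ∈ {4, 8, 16}.

**Density regression.** Binned (k_av = 5), mean-centered feature matrices
feed a SIMPLS PLS1 model; the latent-variable count minimizes the
cross-validated MSE (10-fold observation-level, or 4-fold set-level for
across-experiment transfer). Performance is reported as R² (training) and
Q² = 1 − Σ(y − ŷ)²/Σ(y − ȳ_train)² (held-out).

**Solubility.** Clear points (T, x) per solvent composition are fitted to
the van't Hoff relation for nonideal solutions,

    ln x = −ΔH_d / (R T) + ΔS_d / R

with x the mole-fraction solubility and T in kelvin, giving the enthalpy
and entropy of dissolution; comparing fitted and generating parameters
splits detection error into systematic bias and random scatter.

## Worked example

```python
from crystalsight.cohorts import (detection_experiment_config,
                                  extract_series, ground_truth_models)
from crystalsight.detect import (DetectionConfig, detect_clear, detect_cloud,
                                 detect_transmission, fit_background,
                                 split_segments)
from crystalsight.signals import FilterParams
from crystalsight.synth import simulate_experiment

ratio, loading = (0.80, 0.20), 0.060          # 80:20 solvent, 60 mg/g solute
cfg = detection_experiment_config(ratio, loading, seed=7)
exp = simulate_experiment(cfg, ground_truth_models()[ratio])

series = extract_series(exp, feature_names=["HELM_5"])
bk = fit_background(series)                    # auto: hottest-hold frames
det = DetectionConfig(filter=FilterParams(k_hampel=7, n_sigma=3.0, k_savgol=3))
for kind, sl in split_segments(series):
    seg = series.slice(sl)
    if kind == "cooling":
        print("cloud:", detect_cloud(seg, bk, det).temperature_C,
              "truth:", exp.cloud_point_truth[1])
    if kind == "heating":
        print("clear:", detect_clear(seg, bk, det).temperature_C,
              "truth:", exp.clear_point_truth[1])
clear_t, _ = detect_transmission(series, det)
print("transmission clear:", clear_t.temperature_C)
```

Output (seed 7):

```
cloud: 39.49999999999992 truth: 39.37499999999993
clear: 53.63333333333191 truth: 53.79999999999857
transmission clear: 50.466666666665425
```

The feature-based events land within one frame's temperature step
(0.17 K) of the kinetic ground truth, while the 99.9%-threshold
transmission *clear* point fires 3.3 K early — at that temperature the
vial still holds roughly 5 mg/mL of crystals, the probe's blind spot.
On the full 12-experiment cohort this becomes a mean absolute detection
error of 0.70 mg/mL (features) versus 4.62 mg/mL (transmission), and
van't Hoff enthalpies recovered from feature-based clear points are
within 0.31 kJ/mol of the generating values (transmission: 1.0–6.3
kJ/mol off).

A `crystalsight` CLI wraps the same pipeline for shell use
(`simulate`, `extract`, `condition`, `detect`, `train-plsr`, `predict`,
`fit-solubility`); see `crystalsight --help`.

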
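"""Pre-defined synthetic study designs.

Twelve metastable-zone-width experiments across three solvent ratios (the
detection cohort, mirroring a 70:30 / 80:20 / 90:10 diglyme-water loading
table) and stepwise-heating calibration runs for suspension-density
regression. The ground-truth van't Hoff parameters span the plausible
range for this solute/solvent family (dH_d ~ 20-28 kJ/mol, dS_d ~ 34-43
J/(mol K), both increasing with the water fraction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .detect import (DetectionConfig, detect_clear, detect_cloud,
                     detect_transmission, detection_mae, fit_background,
                     optimize_filters, split_segments)
from .features.extractor import FrameFeatureExtractor
from .signals import FeatureSeries
from .synth import (ExperimentConfig, SyntheticExperiment, mszw_profile,
                    simulate_experiment, staircase_profile)
from .thermo import SolubilityModel, x_gg_to_mol

__all__ = [
    "ground_truth_models", "DETECTION_LOADINGS", "detection_experiment_config",
    "detection_cohort", "calibration_config", "extract_series",
    "calibration_observations", "run_detection_study",
]


def ground_truth_models() -> dict[tuple, SolubilityModel]:
    """Ground-truth solubility models per (DIG, WAT) solvent mass ratio."""
    return {
        (0.70, 0.30): SolubilityModel(dH_d=28000.0, dS_d=42.9),
        (0.80, 0.20): SolubilityModel(dH_d=24100.0, dS_d=38.5),
        (0.90, 0.10): SolubilityModel(dH_d=20100.0, dS_d=34.1),
    }


#: (solvent_ratio, solute loading in g solute / g solvent) per experiment
DETECTION_LOADINGS = (
    ((0.70, 0.30), 0.052), ((0.70, 0.30), 0.038),
    ((0.70, 0.30), 0.027), ((0.70, 0.30), 0.014),
    ((0.80, 0.20), 0.078), ((0.80, 0.20), 0.060), ((0.80, 0.20), 0.044),
    ((0.90, 0.10), 0.150), ((0.90, 0.10), 0.120), ((0.90, 0.10), 0.101),
    ((0.90, 0.10), 0.084), ((0.90, 0.10), 0.073),
)


def _saturation_T(solub: SolubilityModel, x_gg: float, ratio) -> float:
    return solub.solubility_temperature(x_gg_to_mol(x_gg, ratio))


def _nucleation_T(solub: SolubilityModel, x_gg: float, ratio,
                  S_nuc: float) -> float:
    return solub.solubility_temperature(x_gg_to_mol(x_gg / S_nuc, ratio))


def detection_experiment_config(ratio, x_gg: float, seed: int,
                                solub: SolubilityModel | None = None,
                                image_shape=(480, 640), fps: float = 0.05,
                                rate: float = 0.5,
                                hold_min: float = 30.0) -> ExperimentConfig:
    """Metastable-zone-width design for one loading: background hold above
    saturation, slow cooling through nucleation, slow re-heating through
    dissolution."""
    solub = solub or ground_truth_models()[ratio]
    base = ExperimentConfig(solvent_ratio=ratio, solute_load=x_gg * 1000.0,
                            image_shape=image_shape, fps=fps, seed=seed)
    T_sat = _saturation_T(solub, x_gg, ratio)
    T_nuc = _nucleation_T(solub, x_gg, ratio, base.S_nuc)
    profile = mszw_profile(T_max=round(T_sat + 8.0, 1),
                           T_min=round(T_nuc - 6.0, 1),
                           rate=rate, hold_min=hold_min)
    return replace(base, profile=tuple(profile))


def detection_cohort(seed: int = 0, image_shape=(480, 640),
                     fps: float = 0.05, render: bool = True
                     ) -> list[SyntheticExperiment]:
    """The 12-experiment synthetic detection cohort."""
    models = ground_truth_models()
    out = []
    for i, (ratio, x_gg) in enumerate(DETECTION_LOADINGS):
        cfg = detection_experiment_config(ratio, x_gg, seed=seed * 1000 + i,
                                          image_shape=image_shape, fps=fps)
        out.append(simulate_experiment(cfg, models[ratio], render=render))
    return out


def calibration_config(ratio=(0.70, 0.30), x_gg: float = 0.052,
                       seed: int = 0, image_shape=(96, 128),
                       fps: float = 0.05, step_K: float = 5.0,
                       hold_min: float = 30.0,
                       solub: SolubilityModel | None = None) -> ExperimentConfig:
    """Stepwise-heating calibration design: start suspended, heat in 5 K
    steps with isothermal holds to above saturation."""
    solub = solub or ground_truth_models()[ratio]
    T_sat = _saturation_T(solub, x_gg, ratio)
    T_lo = 5.0 * math.floor((T_sat - 25.0) / 5.0)
    T_hi = 5.0 * math.ceil((T_sat + 5.0) / 5.0)
    profile = staircase_profile(T_lo, T_hi, step_K=step_K, hold_min=hold_min)
    return ExperimentConfig(solvent_ratio=ratio, solute_load=x_gg * 1000.0,
                            profile=tuple(profile), image_shape=image_shape,
                            fps=fps, seed=seed)


def extract_series(exp: SyntheticExperiment, feature_names=None,
                   registry=None, background_frame=None,
                   indices=None) -> FeatureSeries:
    """Extract a FeatureSeries from (a subset of) an experiment's frames."""
    ex = FrameFeatureExtractor(registry=registry, feature_names=feature_names)
    ex.fit(background=background_frame)
    frames = exp.frames if indices is None else [exp.frames[i] for i in indices]
    idx = np.arange(len(exp.frames)) if indices is None else np.asarray(indices)
    values = ex.transform(frames)
    return FeatureSeries(exp.times_s[idx], exp.temperatures_C[idx],
                         exp.transmission[idx], values,
                         list(ex.feature_names_out_))


def _hold_windows(exp: SyntheticExperiment, n_last: int,
                  settle_min: float = 5.0) -> list[np.ndarray]:
    """Frame indices of the last ``n_last`` frames of every isothermal hold
    (after an equilibration margin), in profile order."""
    temps = exp.temperatures_C
    windows = []
    # contiguous runs of constant temperature are the isothermal holds
    run_start = 0
    for i in range(1, len(temps) + 1):
        if i == len(temps) or temps[i] != temps[run_start]:
            run = np.arange(run_start, i)
            dur_min = (exp.times_s[run[-1]] - exp.times_s[run[0]]) / 60.0
            if run.size >= n_last and dur_min >= settle_min:
                windows.append(run[-n_last:])
            run_start = i
    return windows


def calibration_observations(exp: SyntheticExperiment, n_per_level: int = 25,
                             registry=None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Full-registry feature matrix, density response and level labels from
    the calibration windows (end of every isothermal hold) of a
    stepwise-heating run."""
    windows = _hold_windows(exp, n_per_level)
    idx = np.concatenate(windows)
    series = extract_series(exp, indices=idx)
    y = exp.x_c_truth[idx]
    labels = np.concatenate([np.full(w.size, wi) for wi, w in enumerate(windows)])
    return series.values, y, labels


def run_detection_study(seed: int = 0, image_shape=(480, 640),
                        fps: float = 0.05, n_nuc: float = 4.0,
                        training_indices=(0, 4, 7)) -> dict:
    """The full clear/cloud detection study on the 12-experiment cohort.

    Simulates the cohort, extracts the HELM_5 feature signal, fits a
    background model per experiment, grid-optimizes the conditioning
    parameters on three training experiments (one per solvent ratio)
    against the simulation ground truth, then detects clear/cloud points
    with the feature criterion and with the 99.9% transmission threshold
    on every experiment. Returns per-experiment events, detection MAEs
    of both methods and per-solvent-ratio van't Hoff fits/biases.
    """
    models = ground_truth_models()
    exps = detection_cohort(seed=seed, image_shape=image_shape, fps=fps)
    prepared = []
    for exp in exps:
        series = extract_series(exp, feature_names=["HELM_5"])
        bk = fit_background(series)
        segs = split_segments(series)
        cool = next(sl for k, sl in segs if k == "cooling")
        heat = next(sl for k, sl in segs if k == "heating")
        prepared.append({"exp": exp, "series": series, "bk": bk,
                         "cool": cool, "heat": heat})

    training = []
    for ti in training_indices:
        p = prepared[ti]
        exp = p["exp"]
        truth = {"clear": (p["heat"], exp.clear_point_truth[1]),
                 "cloud": (p["cool"], exp.cloud_point_truth[1])}
        training.append((p["series"], p["bk"], truth))
    best_filter, mse_table = optimize_filters(training)

    cfg = DetectionConfig(n_nuc=n_nuc, filter=best_filter)
    events = []
    for p, (ratio, x_gg) in zip(prepared, DETECTION_LOADINGS):
        exp = p["exp"]
        clear_f = detect_clear(p["series"].slice(p["heat"]), p["bk"], cfg)
        cloud_f = detect_cloud(p["series"].slice(p["cool"]), p["bk"], cfg)
        # transmission comparison on the dynamic (cool + heat) portion
        dyn = p["series"].slice(slice(p["cool"].start, p["heat"].stop))
        clear_t, cloud_t = detect_transmission(dyn, cfg)
        events.append({
            "ratio": ratio, "x_gg": x_gg,
            "clear_truth": exp.clear_point_truth,
            "cloud_truth": exp.cloud_point_truth,
            "clear_feature": clear_f, "cloud_feature": cloud_f,
            "clear_transmission": clear_t, "cloud_transmission": cloud_t,
            "temperature_step": float(np.median(np.abs(np.diff(
                p["series"].temperatures_C[p["heat"]])))),
        })

    def _mae(kind: str) -> dict:
        total_abs, n = 0.0, 0
        for ratio in models:
            pts = [(e[kind].temperature_C, e["x_gg"], e["ratio"])
                   for e in events if e["ratio"] == ratio and e[kind].detected]
            if not pts:
                continue
            out = detection_mae(pts, models[ratio])
            total_abs += sum(abs(r) for r in out["residuals_gg"])
            n += len(out["residuals_gg"])
        rho = exps[0].config.solvent_density
        return {"mae_gg": total_abs / n, "mae_mg_per_mL": total_abs / n * rho * 1000.0,
                "n": n}

    def _fits(kind: str) -> dict:
        fits = {}
        for ratio, truth_model in models.items():
            pts = [(e[kind].temperature_C, x_gg_to_mol(e["x_gg"], ratio))
                   for e in events if e["ratio"] == ratio and e[kind].detected]
            from .thermo import fit_vanthoff, solubility_bias
            fit = fit_vanthoff(pts)
            fits[ratio] = {"fit": fit, "truth": truth_model,
                           "bias": solubility_bias(fit, truth_model)}
        return fits

    return {
        "events": events,
        "filter": best_filter,
        "mse_table": mse_table,
        "mae_feature": _mae("clear_feature"),
        "mae_transmission": _mae("clear_transmission"),
        "vanthoff_feature": _fits("clear_feature"),
        "vanthoff_transmission": _fits("clear_transmission"),
    }
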
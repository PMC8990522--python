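"""Clear/cloud point detection.

The feature-based criterion references a background model (per-feature
median m_bk and standard deviation sigma_bk over clear-solution frames):
a cloud point is the first sustained divergence of the conditioned feature
signal outside the band m_bk +/- n_Nuc sigma_bk; a clear point is the
first sustained (and final) convergence back into that band. A fixed
99.9%-threshold detector on the smoothed transmission signal is provided
for comparison, and the conditioning parameters can be grid-optimized
against ground-truth events by minimizing the temperature MSE.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.base import BaseEstimator

from .signals import FeatureSeries, FilterParams, condition
from .thermo import SolubilityModel, x_mol_to_gg

__all__ = [
    "BackgroundModel", "DetectionConfig", "DetectionResult",
    "fit_background", "detect_cloud", "detect_clear", "detect_transmission",
    "split_segments", "optimize_filters", "detection_mae", "EventDetector",
]

#: number of clear-solution frames used for the background model
N_BACKGROUND_FRAMES = 15


@dataclass(frozen=True)
class BackgroundModel:
    """Per-feature median and spread over clear-solution frames."""

    feature_names: tuple
    m_bk: np.ndarray
    sigma_bk: np.ndarray
    n_frames: int
    source_temperature_C: float

    def __post_init__(self):
        if self.n_frames < 2:
            raise ValueError("background model needs >= 2 frames")
        if np.any(self.sigma_bk < 0):
            raise ValueError("sigma_bk must be >= 0")

    def band(self, feature_name: str, n_nuc: float) -> tuple[float, float]:
        i = self.feature_names.index(feature_name)
        m, s = self.m_bk[i], self.sigma_bk[i]
        return m - n_nuc * s, m + n_nuc * s


@dataclass(frozen=True)
class DetectionConfig:
    feature_name: str = "HELM_5"
    n_nuc: float = 4.0              # band half-width in background SDs
    persistence: int = 3            # consecutive samples required
    filter: FilterParams = field(
        default_factory=lambda: FilterParams(k_hampel=29, n_sigma=0.1,
                                             k_savgol=11))
    transmission_threshold: float = 99.9

    def __post_init__(self):
        if self.n_nuc <= 0:
            raise ValueError("n_nuc must be > 0")
        if self.persistence < 1:
            raise ValueError("persistence must be >= 1")


@dataclass(frozen=True)
class DetectionResult:
    event_kind: str                 # {"clear", "cloud"}
    detected: bool
    time_s: float = float("nan")
    temperature_C: float = float("nan")
    method: str = "feature"         # {"feature", "transmission"}
    index: int = -1


def fit_background(series: FeatureSeries,
                   frame_indices=None) -> BackgroundModel:
    """Per-feature median and SD over clear-solution frames.

    When ``frame_indices`` is omitted, the last 15 frames of the hold at
    the maximum temperature are selected automatically (the raw,
    unconditioned values enter the model so the band width reflects the
    measurement noise the detector faces).
    """
    if frame_indices is None:
        temps = series.temperatures_C
        t_max = temps.max()
        at_max = np.flatnonzero(temps >= t_max - 1e-6)
        frame_indices = at_max[-N_BACKGROUND_FRAMES:]
    idx = np.asarray(list(frame_indices), dtype=int)
    if idx.size < 2:
        raise ValueError("need >= 2 background frames")
    block = series.values[idx]
    return BackgroundModel(
        feature_names=tuple(series.names),
        m_bk=np.median(block, axis=0),
        sigma_bk=block.std(axis=0, ddof=1),
        n_frames=int(idx.size),
        source_temperature_C=float(series.temperatures_C[idx].mean()),
    )


def _conditioned(series: FeatureSeries, cfg: DetectionConfig) -> np.ndarray:
    return condition(series.feature(cfg.feature_name), cfg.filter)


def _result(series: FeatureSeries, kind: str, i: int | None,
            method: str = "feature") -> DetectionResult:
    if i is None:
        return DetectionResult(kind, False, method=method)
    return DetectionResult(kind, True, time_s=float(series.times_s[i]),
                           temperature_C=float(series.temperatures_C[i]),
                           method=method, index=int(i))


def detect_cloud(series: FeatureSeries, bk: BackgroundModel,
                 cfg: DetectionConfig, signal=None) -> DetectionResult:
    """First sustained divergence of the conditioned signal outside the
    background band (first sample of the first out-of-band run of length
    >= persistence). A zero-width band (sigma_bk = 0) makes any deviation
    trigger."""
    y = _conditioned(series, cfg) if signal is None else np.asarray(signal)
    lo, hi = bk.band(cfg.feature_name, cfg.n_nuc)
    out = (y < lo) | (y > hi)
    i = _first_run(out, cfg.persistence)
    return _result(series, "cloud", i)


def detect_clear(series: FeatureSeries, bk: BackgroundModel,
                 cfg: DetectionConfig, signal=None) -> DetectionResult:
    """First sample of the final inside-band run: the signal must stay
    inside the band for >= persistence samples and through the series end
    (sustained convergence; transient dips back into the band are
    ignored)."""
    y = _conditioned(series, cfg) if signal is None else np.asarray(signal)
    lo, hi = bk.band(cfg.feature_name, cfg.n_nuc)
    inside = (y >= lo) & (y <= hi)
    if not inside[-1]:
        return _result(series, "clear", None)
    # start of the final inside-run
    start = len(inside) - 1
    while start > 0 and inside[start - 1]:
        start -= 1
    if len(inside) - start < cfg.persistence:
        return _result(series, "clear", None)
    return _result(series, "clear", start)


def _first_run(mask: np.ndarray, persistence: int):
    run = 0
    for i, m in enumerate(mask):
        run = run + 1 if m else 0
        if run >= persistence:
            return i - persistence + 1
    return None


def split_segments(series: FeatureSeries, min_len: int = 5):
    """Partition a series into (kind, slice) segments with kind in
    {"heating", "cooling", "hold"}, from the sign of the temperature
    trend."""
    dT = np.diff(series.temperatures_C)
    sign = np.sign(np.round(dT, 9))
    segments = []
    start = 0
    for i in range(1, len(sign)):
        if sign[i] != sign[start]:
            segments.append((sign[start], slice(start, i + 1)))
            start = i
    segments.append((sign[start], slice(start, len(series))))
    kinds = {1.0: "heating", -1.0: "cooling", 0.0: "hold"}
    return [(kinds[s], sl) for s, sl in segments
            if sl.stop - sl.start >= min_len]


def detect_transmission(series: FeatureSeries, cfg: DetectionConfig
                        ) -> tuple[DetectionResult, DetectionResult]:
    """Threshold detection on the smoothed transmission channel.

    The channel is conditioned with the fixed transmission settings
    (Hampel window 7 / 3 sigma, order-1 Savitzky-Golay window 9); the
    clear point is the first smoothed sample above the threshold on a
    heating segment, the cloud point the first below it on a cooling
    segment.
    """
    sm = condition(series.transmission_pct, FilterParams())
    thr = cfg.transmission_threshold
    clear_i = cloud_i = None
    for kind, sl in split_segments(series):
        seg = np.arange(sl.start, sl.stop)
        if kind == "heating" and clear_i is None:
            above = np.flatnonzero(sm[sl] > thr)
            if above.size:
                clear_i = int(seg[above[0]])
        if kind == "cooling" and cloud_i is None:
            below = np.flatnonzero(sm[sl] < thr)
            if below.size:
                cloud_i = int(seg[below[0]])
    return (_result(series, "clear", clear_i, method="transmission"),
            _result(series, "cloud", cloud_i, method="transmission"))


class EventDetector(BaseEstimator):
    """Background-referenced clear/cloud detector, estimator-style.

    fit() learns the background model from clear-solution frames of a
    reference series; detect_clear/detect_cloud apply the divergence /
    convergence criterion to (segments of) a series.
    """

    def __init__(self, config: DetectionConfig | None = None):
        self.config = config

    def _cfg(self) -> DetectionConfig:
        return self.config if self.config is not None else DetectionConfig()

    def fit(self, series: FeatureSeries, frame_indices=None):
        self.background_ = fit_background(series, frame_indices)
        return self

    def detect_cloud(self, series: FeatureSeries) -> DetectionResult:
        return detect_cloud(series, self.background_, self._cfg())

    def detect_clear(self, series: FeatureSeries) -> DetectionResult:
        return detect_clear(series, self.background_, self._cfg())


def _event_sq_errors(series: FeatureSeries, bk: BackgroundModel,
                     cfg: DetectionConfig, truth: dict) -> list[float]:
    """Squared temperature errors for the annotated events of one series.

    ``truth`` maps "clear"/"cloud" to (segment_slice, temperature_C).
    Undetected events are penalized with the segment's squared
    temperature span.
    """
    errs = []
    for kind, (sl, T_truth) in truth.items():
        seg = series.slice(sl)
        sig = condition(seg.feature(cfg.feature_name), cfg.filter)
        if kind == "cloud":
            r = detect_cloud(seg, bk, cfg, signal=sig)
        else:
            r = detect_clear(seg, bk, cfg, signal=sig)
        if r.detected:
            errs.append((r.temperature_C - T_truth)**2)
        else:
            span = float(seg.temperatures_C.max() - seg.temperatures_C.min())
            errs.append(span**2)
    return errs


def optimize_filters(training, feature_name: str = "HELM_5",
                     k_hampel_grid=(3, 7, 15, 29),
                     n_sigma_grid=(0.1, 1.0, 3.0),
                     k_savgol_grid=(3, 5, 9, 11),
                     n_nuc_levels=(4.0, 8.0, 16.0),
                     persistence: int = 3):
    """Exhaustive grid search of the conditioning parameters.

    ``training`` is a list of (series, background_model, truth) triples
    where ``truth`` maps event kinds to (segment_slice, true_temperature).
    The objective is the mean squared detected-vs-true temperature error
    over all training events and all n_Nuc band levels; ties resolve to
    the smallest (k_Hpl, k_SG) lexicographically. Returns
    (best FilterParams, MSE table as a dict keyed by the grid point).
    """
    if not training:
        raise ValueError("need >= 1 training experiment")
    grid = list(itertools.product(k_hampel_grid, n_sigma_grid, k_savgol_grid))
    if not grid:
        raise ValueError("empty parameter grid")
    table = {}
    best = None
    for k_hpl, n_sig, k_sg in grid:
        fp = FilterParams(k_hampel=k_hpl, n_sigma=n_sig, k_savgol=k_sg)
        errs = []
        for series, bk, truth in training:
            for n_nuc in n_nuc_levels:
                cfg = DetectionConfig(feature_name=feature_name, n_nuc=n_nuc,
                                      persistence=persistence, filter=fp)
                errs.extend(_event_sq_errors(series, bk, cfg, truth))
        mse = float(np.mean(errs))
        table[(k_hpl, n_sig, k_sg)] = mse
        key = (mse, k_hpl, k_sg)
        if best is None or key < best[0]:
            best = (key, fp)
    return best[1], table


def detection_mae(clear_points, truth: SolubilityModel,
                  solvent_density: float = None):
    """Mean absolute detection error expressed as residual suspension mass.

    ``clear_points`` is a list of (T_detected_C, loading_x_gg,
    solvent_ratio). The residual of each experiment is the loaded solute
    fraction minus the ground-truth dissolved fraction at the detected
    temperature; the MAE is returned in g/g and mg/mL (via the solvent
    density). Detections whose temperature falls outside the truth
    model's invertible range are excluded with a count of exclusions.
    """
    from .thermo import DEFAULT_SOLVENT_DENSITY
    rho = solvent_density if solvent_density is not None else DEFAULT_SOLVENT_DENSITY
    residuals = []
    excluded = 0
    for T_det, x_gg_loaded, ratio in clear_points:
        try:
            x_hat = x_mol_to_gg(truth.predict_x(float(T_det)), ratio)
        except (ValueError, OverflowError):
            excluded += 1
            continue
        residuals.append(x_gg_loaded - x_hat)
    if not residuals:
        raise ValueError("no usable clear points")
    mae_gg = float(np.mean(np.abs(residuals)))
    return {"mae_gg": mae_gg, "mae_mg_per_mL": mae_gg * rho * 1000.0,
            "residuals_gg": residuals, "excluded": excluded}
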
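"""Background-referenced event detection and filter optimization."""

import numpy as np
import pytest

from crystalsight.detect import (BackgroundModel, DetectionConfig,
                                 detect_clear, detect_cloud,
                                 detect_transmission, detection_mae,
                                 fit_background, optimize_filters,
                                 split_segments)
from crystalsight.signals import FeatureSeries, FilterParams
from crystalsight.thermo import SolubilityModel, x_mol_to_gg


def _series(values, temps=None, trans=None, names=("HELM_5",)):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] == 1 and len(names) == 1:
        values = values.T
    n = values.shape[0]
    return FeatureSeries(np.arange(n, dtype=float) * 10.0,
                         np.zeros(n) if temps is None else np.asarray(temps, float),
                         np.full(n, 100.0) if trans is None else np.asarray(trans, float),
                         values, list(names))


def _bk(m=1.0, sigma=0.01):
    return BackgroundModel(("HELM_5",), np.array([m]), np.array([sigma]),
                           n_frames=15, source_temperature_C=60.0)


RAW_CFG = DetectionConfig(filter=FilterParams(k_hampel=3, n_sigma=np.inf,
                                              k_savgol=3))


def test_fit_background_median_and_sd():
    vals = np.ones((20, 1))
    vals[4, 0] = 100.0   # single outlier frame
    series = _series(vals[:, 0])
    bk = fit_background(series, frame_indices=range(5))
    assert bk.m_bk[0] == 1.0            # median robust to the outlier
    series2 = _series(np.ones(20))
    bk2 = fit_background(series2, frame_indices=range(15))
    assert bk2.sigma_bk[0] == 0.0


def test_fit_background_autoselects_max_temperature_hold():
    temps = np.concatenate([np.full(30, 40.0), np.full(30, 70.0)])
    vals = np.concatenate([np.full(30, 9.0), np.full(30, 2.0)])
    bk = fit_background(_series(vals, temps=temps))
    assert bk.m_bk[0] == 2.0
    assert bk.n_frames == 15
    assert bk.source_temperature_C == 70.0


def test_cloud_detected_at_first_of_persistent_run():
    sig = np.concatenate([np.ones(50), np.full(30, 1.0 + 10 * 0.01)])
    series = _series(sig)
    r = detect_cloud(series, _bk(), DetectionConfig(
        n_nuc=4.0, persistence=3, filter=RAW_CFG.filter), signal=sig)
    assert r.detected and r.index == 50


def test_cloud_not_detected_on_background_signal():
    series = _series(np.ones(60))
    r = detect_cloud(series, _bk(), RAW_CFG, signal=series.feature("HELM_5"))
    assert not r.detected


def test_cloud_monotone_in_band_width():
    rng = np.random.default_rng(0)
    sig = np.concatenate([np.ones(40), 1.0 + 0.01 * np.arange(1, 61)])
    sig += rng.normal(0, 1e-4, sig.size)
    series = _series(sig)
    times = []
    for n_nuc in (4.0, 8.0, 16.0):
        cfg = DetectionConfig(n_nuc=n_nuc, filter=RAW_CFG.filter)
        r = detect_cloud(series, _bk(), cfg, signal=sig)
        times.append(r.time_s)
    assert times[0] <= times[1] <= times[2]


def test_clear_detection_ignores_transient_dips():
    # dips into the band for 2 samples, exits, then converges at index 70
    sig = np.full(100, 1.2)
    sig[30:32] = 1.0
    sig[70:] = 1.0
    series = _series(sig)
    cfg = DetectionConfig(persistence=3, filter=RAW_CFG.filter)
    r = detect_clear(series, _bk(), cfg, signal=sig)
    assert r.detected and r.index == 70


def test_clear_detects_first_sample_when_always_inside():
    sig = np.ones(40)
    r = detect_clear(_series(sig), _bk(), RAW_CFG, signal=sig)
    assert r.detected and r.index == 0


def test_clear_undetected_when_never_converging():
    sig = np.full(40, 2.0)
    r = detect_clear(_series(sig), _bk(), RAW_CFG, signal=sig)
    assert not r.detected


def test_transmission_threshold_detection():
    # heating then cooling; transmission recovers above 99.9 during heating
    temps = np.concatenate([np.linspace(30, 60, 60), np.linspace(60, 30, 60)])
    trans = np.concatenate([np.linspace(99.0, 100.0, 60), np.linspace(100.0, 98.0, 60)])
    series = _series(np.ones(120), temps=temps, trans=trans)
    clear, cloud = detect_transmission(series, DetectionConfig())
    assert clear.detected and cloud.detected
    assert clear.method == "transmission"
    assert 99.0 <= trans[clear.index + 1] <= 100.0
    assert cloud.index > 60


def test_transmission_constant_full_never_detects_cloud():
    temps = np.linspace(60, 30, 50)
    series = _series(np.ones(50), temps=temps, trans=np.full(50, 100.0))
    _, cloud = detect_transmission(series, DetectionConfig())
    assert not cloud.detected


def test_split_segments_kinds():
    temps = np.concatenate([np.full(20, 60.0), np.linspace(60, 40, 30),
                            np.linspace(40, 60, 30), np.full(20, 60.0)])
    series = _series(np.ones(100), temps=temps)
    kinds = [k for k, _ in split_segments(series)]
    assert kinds == ["hold", "cooling", "heating", "hold"]


# ---------------------------------------------------------- optimization

def _training_set():
    """Step signal with known event indices and a temperature ramp."""
    n = 120
    temps = np.linspace(50, 26, n)          # cooling segment
    sig = np.ones(n)
    sig[60:] = 1.5                           # cloud at index 60 -> T = 38.07...
    series = _series(sig, temps=temps)
    truth = {"cloud": (slice(0, n), float(temps[60]))}
    return series, _bk(sigma=0.001), truth


def test_single_point_grid_returned():
    training = [_training_set()]
    fp, table = optimize_filters(training, k_hampel_grid=(3,),
                                 n_sigma_grid=(3.0,), k_savgol_grid=(3,))
    assert (fp.k_hampel, fp.n_sigma, fp.k_savgol) == (3, 3.0, 3)
    assert len(table) == 1


def test_grid_search_objective_matches_recomputation():
    training = [_training_set()]
    fp, table = optimize_filters(training)
    # re-evaluate the winning objective independently
    from crystalsight.detect import _event_sq_errors
    errs = []
    series, bk, truth = training[0]
    for n_nuc in (4.0, 8.0, 16.0):
        cfg = DetectionConfig(n_nuc=n_nuc, persistence=3,
                              filter=fp)
        errs.extend(_event_sq_errors(series, bk, cfg, truth))
    assert table[(fp.k_hampel, fp.n_sigma, fp.k_savgol)] == pytest.approx(
        float(np.mean(errs)))
    assert min(table.values()) == table[(fp.k_hampel, fp.n_sigma, fp.k_savgol)]


def test_optimize_requires_training_data():
    with pytest.raises(ValueError):
        optimize_filters([])


# ------------------------------------------------------------------ MAE

def test_detection_mae_zero_on_truth_curve():
    truth = SolubilityModel(dH_d=24100.0, dS_d=38.5)
    ratio = (0.80, 0.20)
    pts = []
    for xgg in (0.044, 0.060, 0.078):
        from crystalsight.thermo import x_gg_to_mol
        T = truth.solubility_temperature(x_gg_to_mol(xgg, ratio))
        pts.append((T, xgg, ratio))
    out = detection_mae(pts, truth)
    assert out["mae_gg"] == pytest.approx(0.0, abs=1e-12)


def test_detection_mae_single_offset_point():
    truth = SolubilityModel(dH_d=24100.0, dS_d=38.5)
    ratio = (0.80, 0.20)
    T = truth.solubility_temperature(0.01)
    loaded = x_mol_to_gg(0.01, ratio) + 0.004
    out = detection_mae([(T, loaded, ratio)], truth)
    assert out["mae_gg"] == pytest.approx(0.004, abs=1e-12)
    assert out["mae_mg_per_mL"] == pytest.approx(0.004 * 0.95 * 1000.0, rel=1e-9)
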
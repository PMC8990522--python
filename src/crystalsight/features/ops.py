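"""Per-frame image feature operations.

All features are computed in double precision on the raw 0-255 intensity
scale. Neighborhood operations use replicate ("nearest") padding; Brenner's
two-point differences are restricted to the valid (unpadded) support.
Variances are population variances throughout.
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy import ndimage

from ..frames import GrayFrame

__all__ = [
    "global_stats",
    "histogram_params",
    "helm",
    "gradient_focus",
    "local_variance_features",
    "range_features",
    "range_gauss_features",
    "gauss_gradient_features",
    "dog_features",
    "wavelet_features",
]

# 3x3 gradient kernels (correlation convention; Gx responds to column-wise
# increase, Gy to row-wise increase).
SOBEL_GX = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])
SOBEL_GY = SOBEL_GX.T
PREWITT_GX = np.array([[-1.0, 0.0, 1.0], [-1.0, 0.0, 1.0], [-1.0, 0.0, 1.0]])
PREWITT_GY = PREWITT_GX.T
LAPLACE_K = np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]])


def _pixels(frame) -> np.ndarray:
    if isinstance(frame, GrayFrame):
        return frame.as_float()
    return np.asarray(frame, dtype=np.float64)


def _check_odd(k: int) -> None:
    if k % 2 == 0 or k < 3:
        raise ValueError(f"kernel size must be odd and >= 3, got {k}")


def _hist256(img: np.ndarray) -> np.ndarray:
    return np.bincount(np.clip(np.rint(img), 0, 255).astype(np.intp).ravel(),
                       minlength=256).astype(np.float64)


def shannon_entropy_bits(img: np.ndarray) -> float:
    """Shannon entropy (bits) of the 256-bin normalized intensity histogram."""
    h = _hist256(img)
    p = h / h.sum()
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def global_stats(frame) -> dict[str, float]:
    """Six global intensity statistics of the raw image.

    IntM: mean; IntV: population variance; IntIdxD: index of dispersion
    IntV/IntM (0 when IntM = 0); IntSkew/IntKurt: skewness and excess
    kurtosis (0 for a constant image); IntEnt: histogram entropy in bits.
    """
    x = _pixels(frame)
    m = float(x.mean())
    v = float(x.var())
    if v > 0:
        d = x - m
        skew = float((d**3).mean() / v**1.5)
        kurt = float((d**4).mean() / v**2 - 3.0)
    else:
        skew = 0.0
        kurt = 0.0
    return {
        "IntM": m,
        "IntV": v,
        "IntIdxD": v / m if m != 0 else 0.0,
        "IntSkew": skew,
        "IntKurt": kurt,
        "IntEnt": shannon_entropy_bits(x),
    }


def histogram_params(frame, background=None) -> tuple[dict[str, float], bool]:
    """Fifteen parameters of the 256-bin pixel intensity histogram.

    ``background`` supplies the reference frame whose P5/P95 define the
    HistSumBK / HistTailBK cuts. Without one, the frame's own percentiles
    are used; the second return value flags that self-referenced fallback.
    """
    x = _pixels(frame)
    h = _hist256(x)
    n = h.sum()
    occupied = np.flatnonzero(h)
    lo, hi = float(occupied[0]), float(occupied[-1])
    mode_bin = int(np.argmax(h))
    mode_height = h[mode_bin]
    # full width at half of the mode height, in gray levels
    at_least_half = np.flatnonzero(h >= mode_height / 2.0)
    fwhm = float(at_least_half[-1] - at_least_half[0])
    p5, p25, med, p75, p95 = (float(np.percentile(x, q)) for q in (5, 25, 50, 75, 95))
    self_ref = background is None
    ref = x if self_ref else _pixels(background)
    bk_lo = float(np.percentile(ref, 5))
    bk_hi = float(np.percentile(ref, 95))
    params = {
        "HistMin": lo,
        "HistMax": hi,
        "HistSpan": hi - lo,
        "HistMode": float(mode_bin),
        "HistModeFrac": float(mode_height / n),
        "HistMedian": med,
        "HistP5": p5,
        "HistP25": p25,
        "HistP75": p75,
        "HistP95": p95,
        "HistIQR": p75 - p25,
        "HistNBins": float(occupied.size),
        "HistFWHM": fwhm,
        "HistSumBK": float((x < bk_lo).mean()),
        "HistTailBK": float((x > bk_hi).mean()),
    }
    return params, self_ref


def _local_mean(x: np.ndarray, k: int) -> np.ndarray:
    return ndimage.uniform_filter(x, size=k, mode="nearest")


def _local_var(x: np.ndarray, k: int) -> np.ndarray:
    m = _local_mean(x, k)
    m2 = _local_mean(x * x, k)
    return np.maximum(m2 - m * m, 0.0)


def helm_ratio_image(frame, k: int) -> np.ndarray:
    """Per-pixel intensity-to-local-mean ratio, oriented to be >= 1.

    The ratio is max(I, mu_k)/min(I, mu_k) with both numerator and
    denominator floored at one gray level so zero-intensity pixels stay
    finite (a constant-zero frame gives exactly 1).
    """
    _check_odd(k)
    x = _pixels(frame)
    mu = _local_mean(x, k)
    hi = np.maximum(x, mu)
    lo = np.minimum(x, mu)
    return np.maximum(hi, 1.0) / np.maximum(lo, 1.0)


def helm(frame, k: int) -> float:
    """HELM focus measure: mean of the local mean-ratio image (>= 1)."""
    return float(helm_ratio_image(frame, k).mean())


def helm_features(frame, k: int) -> dict[str, float]:
    r = helm_ratio_image(frame, k)
    return {f"HELM_{k}": float(r.mean()), f"HELMV_{k}": float(r.var())}


def gradient_focus(frame) -> dict[str, float]:
    """Gradient- and Laplacian-based focus measures.

    BREN: mean of squared two-point (spacing 2) differences on the valid
    support; TENG: mean Sobel Gx^2+Gy^2; PRWM/PRWV and SOBM/SOBV: mean and
    variance of the Prewitt / Sobel gradient-magnitude image; LAPM/LAPV:
    mean absolute value and variance of the 3x3 Laplacian response.
    """
    x = _pixels(frame)
    d_row = x[2:, :-2] - x[:-2, :-2]
    d_col = x[:-2, 2:] - x[:-2, :-2]
    bren = float((d_row**2 + d_col**2).mean())

    gxs = ndimage.correlate(x, SOBEL_GX, mode="nearest")
    gys = ndimage.correlate(x, SOBEL_GY, mode="nearest")
    teng = float((gxs**2 + gys**2).mean())
    sob_mag = np.hypot(gxs, gys)

    gxp = ndimage.correlate(x, PREWITT_GX, mode="nearest")
    gyp = ndimage.correlate(x, PREWITT_GY, mode="nearest")
    prw_mag = np.hypot(gxp, gyp)

    lap = ndimage.correlate(x, LAPLACE_K, mode="nearest")
    return {
        "BREN": bren,
        "TENG": teng,
        "PRWM": float(prw_mag.mean()),
        "PRWV": float(prw_mag.var()),
        "SOBM": float(sob_mag.mean()),
        "SOBV": float(sob_mag.var()),
        "LAPM": float(np.abs(lap).mean()),
        "LAPV": float(lap.var()),
    }


def local_variance_features(frame, k: int) -> dict[str, float]:
    """GLLV_k: variance of the local-variance image; GLVN_k: its mean
    normalized by the global variance IntV (0 when IntV = 0)."""
    _check_odd(k)
    x = _pixels(frame)
    v = _local_var(x, k)
    gv = x.var()
    return {
        f"GLLV_{k}": float(v.var()),
        f"GLVN_{k}": float(v.mean() / gv) if gv > 0 else 0.0,
    }


def range_image(frame, k: int) -> np.ndarray:
    _check_odd(k)
    x = _pixels(frame)
    return (ndimage.maximum_filter(x, size=k, mode="nearest")
            - ndimage.minimum_filter(x, size=k, mode="nearest"))


def range_features(frame, k: int) -> dict[str, float]:
    """Mean and variance of the k x k range-filtered image."""
    r = range_image(frame, k)
    return {f"RngM_{k}": float(r.mean()), f"RngV_{k}": float(r.var())}


def _gaussian_smooth(x: np.ndarray, k: int) -> np.ndarray:
    sigma = k / 6.0
    radius = (k - 1) // 2
    return ndimage.gaussian_filter(x, sigma=sigma, mode="nearest",
                                   truncate=radius / sigma)


def range_gauss_features(frame, k: int) -> dict[str, float]:
    """Range filter applied to a Gaussian-smoothed frame (sigma = k/6,
    kernel truncated at size k); mean and variance of the result."""
    _check_odd(k)
    x = _pixels(frame)
    sm = _gaussian_smooth(x, k)
    r = (ndimage.maximum_filter(sm, size=k, mode="nearest")
         - ndimage.minimum_filter(sm, size=k, mode="nearest"))
    return {f"RngGaussM_{k}": float(r.mean()), f"RngGaussV_{k}": float(r.var())}


def range_gauss_variance(frame, k: int) -> float:
    return range_gauss_features(frame, k)[f"RngGaussV_{k}"]


def gauss_gradient_features(frame, sigma: float = 2.0) -> dict[str, float]:
    """Mean, variance and maximum of the Gaussian gradient magnitude."""
    x = _pixels(frame)
    g = ndimage.gaussian_gradient_magnitude(x, sigma=sigma, mode="nearest")
    return {"GRGM": float(g.mean()), "GRGV": float(g.var()),
            "GRGMax": float(g.max())}


def dog_features(frame, sigma_lo: float = 2.0, sigma_hi: float = 4.0) -> dict[str, float]:
    """Difference-of-Gaussians band-pass response: mean absolute value and
    variance."""
    x = _pixels(frame)
    d = (ndimage.gaussian_filter(x, sigma_lo, mode="nearest")
         - ndimage.gaussian_filter(x, sigma_hi, mode="nearest"))
    return {"DoGM": float(np.abs(d).mean()), "DoGV": float(d.var())}


def wavelet_features(frame, level: int = 1, wavelet: str = "db6") -> dict[str, float]:
    """Detail statistics of a 2-D discrete wavelet decomposition.

    Uses the orthogonal periodized transform so total energy is preserved.
    WAVS: mean absolute detail coefficient; WAVV: variance of the detail
    coefficients; WAVR: detail-to-approximation energy ratio (0 when the
    approximation energy is 0). Level-2 features carry a "WAV2" prefix and
    are computed from the second-level decomposition of the approximation.
    """
    x = _pixels(frame)
    w = pywt.Wavelet(wavelet)
    if min(x.shape) < w.dec_len:
        raise ValueError(
            f"frame {x.shape} smaller than the {wavelet} filter support ({w.dec_len})")
    approx = x
    for _ in range(level):
        approx, (lh, hl, hh) = pywt.dwt2(approx, w, mode="periodization")
    details = np.concatenate([lh.ravel(), hl.ravel(), hh.ravel()])
    e_d = float((details**2).sum())
    e_a = float((approx**2).sum())
    prefix = "WAV" if level == 1 else f"WAV{level}"
    return {
        f"{prefix}S": float(np.abs(details).mean()),
        f"{prefix}V": float(details.var()),
        f"{prefix}R": e_d / e_a if e_a > 0 else 0.0,
    }
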
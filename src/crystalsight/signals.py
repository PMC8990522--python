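"""Time-series conditioning of feature and transmission signals.

Hampel outlier replacement and order-1 Savitzky-Golay moving-average
smoothing, discrete binning, Pearson correlation, and the peak-resolution
statistic used to rank features by their ability to separate adjacent
suspension-density levels.

Both moving filters use centered windows that shrink symmetrically at the
series ends (no padding), so no data are fabricated where clear/cloud
events may sit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "FilterParams", "FeatureSeries", "ResolutionResult",
    "hampel", "savgol_ma", "condition", "bin_average",
    "peak_resolution", "resolution_ladder", "pearson_corr",
]

#: consistency factor turning the MAD into a Gaussian standard deviation
MAD_SCALE = 1.4826


@dataclass(frozen=True)
class FilterParams:
    """Hampel + Savitzky-Golay conditioning parameters.

    Defaults are the transmission-channel settings (window 7, three local
    standard deviations, order-1 smoothing over 9 samples).
    """

    k_hampel: int = 7
    n_sigma: float = 3.0
    k_savgol: int = 9
    sg_order: int = 1

    def __post_init__(self):
        for k in (self.k_hampel, self.k_savgol):
            if k < 3 or k % 2 == 0:
                raise ValueError("filter windows must be odd and >= 3")
        if self.n_sigma < 0:
            raise ValueError("n_sigma must be >= 0")
        if self.k_savgol <= self.sg_order:
            raise ValueError("smoothing window must exceed the polynomial order")


@dataclass
class FeatureSeries:
    """Per-frame feature matrix with time / temperature / transmission channels."""

    times_s: np.ndarray
    temperatures_C: np.ndarray
    transmission_pct: np.ndarray
    values: np.ndarray          # (n_frames, n_features)
    names: list[str]

    def __post_init__(self):
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.temperatures_C = np.asarray(self.temperatures_C, dtype=float)
        self.transmission_pct = np.asarray(self.transmission_pct, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        n = len(self.times_s)
        if not (len(self.temperatures_C) == len(self.transmission_pct)
                == self.values.shape[0] == n):
            raise ValueError("all channels must have equal length")
        if n > 1 and not np.all(np.diff(self.times_s) > 0):
            raise ValueError("times must be strictly increasing")
        if self.values.shape[1] != len(self.names):
            raise ValueError("feature count must match names")

    def __len__(self) -> int:
        return len(self.times_s)

    def feature(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]

    def slice(self, idx) -> "FeatureSeries":
        return FeatureSeries(self.times_s[idx], self.temperatures_C[idx],
                             self.transmission_pct[idx], self.values[idx],
                             list(self.names))


@dataclass
class ResolutionResult:
    """Pairwise peak resolution of every feature across adjacent levels."""

    feature_names: list[str]
    level_pairs: list[tuple]            # (level_n, level_n1) labels
    mu: np.ndarray                      # (n_levels, n_features) level means
    sigma: np.ndarray                   # (n_levels, n_features) level SDs
    res: np.ndarray                     # (n_pairs, n_features)
    fraction_above_1: float             # n_{Res>1} / n over all cells

    def res_for(self, name: str) -> np.ndarray:
        return self.res[:, self.feature_names.index(name)]


def _half_widths(n: int, k: int) -> np.ndarray:
    h = k // 2
    i = np.arange(n)
    return np.minimum(h, np.minimum(i, n - 1 - i))


def hampel(series, k: int = 7, n_sigma: float = 3.0) -> np.ndarray:
    """Robust moving-window outlier replacement.

    Sample i is replaced by its window median when it deviates from it by
    more than ``n_sigma`` scaled MADs (1.4826 * MAD). Zero deviation is
    never an outlier, so constant series pass through even though their
    MAD is 0.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D series")
    if k < 3 or k % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    n = x.size
    if n == 0:
        return x.copy()
    out = x.copy()
    h = k // 2
    med = np.empty(n)
    mad = np.empty(n)
    if n >= k:
        win = np.lib.stride_tricks.sliding_window_view(x, k)
        m = np.median(win, axis=1)
        med[h:n - h] = m
        mad[h:n - h] = np.median(np.abs(win - m[:, None]), axis=1)
    edge = [i for i in range(n) if i < h or i > n - 1 - h]
    for i in edge:
        hw = min(h, i, n - 1 - i)
        w = x[i - hw:i + hw + 1]
        med[i] = np.median(w)
        mad[i] = np.median(np.abs(w - med[i]))
    dev = np.abs(x - med)
    with np.errstate(invalid="ignore"):   # n_sigma=inf with MAD=0 -> never an outlier
        outlier = dev > n_sigma * MAD_SCALE * mad
    out[outlier] = med[outlier]
    return out


def savgol_ma(series, k: int = 9, order: int = 1) -> np.ndarray:
    """Savitzky-Golay moving smoother with shrunken symmetric edge windows.

    Fits a least-squares polynomial of the given order over each centered
    window and evaluates it at the center. For order 1 on a symmetric
    window this is exactly the window mean, which is how it is computed.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D series")
    if k < 3 or k % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    if k <= order:
        raise ValueError("window must exceed the polynomial order")
    n = x.size
    out = np.empty(n)
    hws = _half_widths(n, k)
    if order <= 1:
        # symmetric window -> centered fit value equals the window mean
        c = np.concatenate([[0.0], np.cumsum(x)])
        lo = np.arange(n) - hws
        hi = np.arange(n) + hws
        out = (c[hi + 1] - c[lo]) / (hi - lo + 1)
        return out
    t = np.arange(n, dtype=float)
    for i in range(n):
        hw = hws[i]
        sl = slice(i - hw, i + hw + 1)
        o = min(order, 2 * hw)
        coef = np.polynomial.polynomial.polyfit(t[sl] - t[i], x[sl], o)
        out[i] = coef[0]
    return out


def condition(series, params: FilterParams) -> np.ndarray:
    """Hampel then Savitzky-Golay, the standard conditioning chain."""
    return savgol_ma(hampel(series, params.k_hampel, params.n_sigma),
                     params.k_savgol, params.sg_order)


def bin_average(values, k_av: int = 5):
    """Non-overlapping consecutive bins of ``k_av`` samples, bin mean per
    channel; a trailing partial bin is dropped. ``k_av = 1`` is the identity.
    """
    if k_av < 1:
        raise ValueError("k_av must be >= 1")
    x = np.asarray(values, dtype=float)
    n_bins = x.shape[0] // k_av
    if x.ndim == 1:
        return x[:n_bins * k_av].reshape(n_bins, k_av).mean(axis=1)
    return x[:n_bins * k_av].reshape(n_bins, k_av, *x.shape[1:]).mean(axis=1)


def peak_resolution(mu_n: float, sigma_n: float, mu_n1: float,
                    sigma_n1: float) -> float:
    """Separation of two (assumed normal) feature distributions.

    Res = |mu_n1 - mu_n| / (2 (sigma_n + sigma_n1)). Res = 1 corresponds to
    the mu +/- 2 sigma envelopes of the two distributions touching, at which
    point at least 95% of draws are correctly classified by the optimal
    single threshold. Degenerate cases: both SDs zero gives +inf for
    distinct means and 0 for equal means.
    """
    if sigma_n < 0 or sigma_n1 < 0:
        raise ValueError("standard deviations must be >= 0")
    d = abs(mu_n1 - mu_n)
    s = sigma_n + sigma_n1
    if s == 0:
        return np.inf if d > 0 else 0.0
    return d / (2.0 * s)


def resolution_ladder(series: FeatureSeries, level_labels,
                      k_av: int = 1) -> ResolutionResult:
    """Peak resolution of every feature between adjacent density levels.

    Levels are taken in order of first appearance in ``level_labels``;
    per-level sample means/SDs (ddof=1) feed the Res statistic, optionally
    after binning each level's block with ``k_av``.
    """
    labels = np.asarray(level_labels)
    if len(labels) != len(series):
        raise ValueError("one level label per frame required")
    ordered = list(dict.fromkeys(labels.tolist()))
    if len(ordered) < 2:
        raise ValueError("need at least 2 levels")
    n_feat = series.values.shape[1]
    mu = np.empty((len(ordered), n_feat))
    sd = np.empty((len(ordered), n_feat))
    for li, lab in enumerate(ordered):
        block = series.values[labels == lab]
        if k_av > 1:
            block = bin_average(block, k_av)
        if block.shape[0] < 2:
            raise ValueError(f"level {lab!r} has fewer than 2 samples")
        mu[li] = block.mean(axis=0)
        sd[li] = block.std(axis=0, ddof=1)
    pairs = list(zip(ordered[:-1], ordered[1:]))
    res = np.empty((len(pairs), n_feat))
    for pi in range(len(pairs)):
        for fi in range(n_feat):
            res[pi, fi] = peak_resolution(mu[pi, fi], sd[pi, fi],
                                          mu[pi + 1, fi], sd[pi + 1, fi])
    frac = float((res > 1).mean())
    return ResolutionResult(list(series.names), pairs, mu, sd, res, frac)


def pearson_corr(series, response) -> float:
    """Pearson correlation coefficient between a feature signal and the
    response (e.g. the crystal suspension density)."""
    x = np.asarray(series, dtype=float)
    y = np.asarray(response, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("series must have equal length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("Pearson r undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)
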
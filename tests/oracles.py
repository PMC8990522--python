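"""Independent brute-force oracles for the image-feature operators.

Everything here is a direct double-loop evaluation of the stated formulas
with explicit replicate padding, deliberately sharing no code with the
package implementations.
"""

import numpy as np


def replicate_pad(x, r):
    return np.pad(np.asarray(x, dtype=float), r, mode="edge")


def window(xp, i, j, k):
    """k x k neighborhood of pixel (i, j) of the r-padded image xp."""
    r = k // 2
    return xp[i:i + k, j:j + k]


def local_mean(x, k):
    x = np.asarray(x, dtype=float)
    r = k // 2
    xp = replicate_pad(x, r)
    out = np.empty_like(x)
    for i in range(x.shape[0]):
        for j in range(x.shape[1]):
            out[i, j] = window(xp, i, j, k).mean()
    return out


def local_var(x, k):
    x = np.asarray(x, dtype=float)
    r = k // 2
    xp = replicate_pad(x, r)
    out = np.empty_like(x)
    for i in range(x.shape[0]):
        for j in range(x.shape[1]):
            w = window(xp, i, j, k)
            out[i, j] = ((w - w.mean()) ** 2).mean()
    return out


def local_range(x, k):
    x = np.asarray(x, dtype=float)
    r = k // 2
    xp = replicate_pad(x, r)
    out = np.empty_like(x)
    for i in range(x.shape[0]):
        for j in range(x.shape[1]):
            w = window(xp, i, j, k)
            out[i, j] = w.max() - w.min()
    return out


def helm_mean(x, k):
    x = np.asarray(x, dtype=float)
    mu = local_mean(x, k)
    total = 0.0
    for i in range(x.shape[0]):
        for j in range(x.shape[1]):
            hi = max(x[i, j], mu[i, j])
            lo = min(x[i, j], mu[i, j])
            total += max(hi, 1.0) / max(lo, 1.0)
    return total / x.size


def correlate3(x, kernel):
    """3x3 correlation with replicate padding, looped."""
    x = np.asarray(x, dtype=float)
    xp = replicate_pad(x, 1)
    out = np.empty_like(x)
    for i in range(x.shape[0]):
        for j in range(x.shape[1]):
            out[i, j] = (xp[i:i + 3, j:j + 3] * kernel).sum()
    return out


def brenner(x):
    x = np.asarray(x, dtype=float)
    rows, cols = x.shape
    total = 0.0
    count = 0
    for i in range(rows - 2):
        for j in range(cols - 2):
            total += (x[i + 2, j] - x[i, j]) ** 2 + (x[i, j + 2] - x[i, j]) ** 2
            count += 1
    return total / count


def gaussian_smooth(x, k):
    """Separable truncated Gaussian (sigma = k/6, radius (k-1)/2),
    replicate padding, built from first principles."""
    x = np.asarray(x, dtype=float)
    sigma = k / 6.0
    r = (k - 1) // 2
    t = np.arange(-r, r + 1)
    g = np.exp(-0.5 * (t / sigma) ** 2)
    g /= g.sum()
    kern = np.outer(g, g)
    xp = replicate_pad(x, r)
    out = np.empty_like(x)
    for i in range(x.shape[0]):
        for j in range(x.shape[1]):
            out[i, j] = (xp[i:i + k, j:j + k] * kern).sum()
    return out


def hampel_direct(x, k, n_sigma):
    """Window-wise Hampel with symmetric shrunken edge windows."""
    x = np.asarray(x, dtype=float)
    n = x.size
    out = x.copy()
    for i in range(n):
        h = min(k // 2, i, n - 1 - i)
        w = x[i - h:i + h + 1]
        med = np.median(w)
        mad = np.median(np.abs(w - med))
        if abs(x[i] - med) > n_sigma * 1.4826 * mad:
            out[i] = med
    return out


def savgol_direct(x, k, order):
    """Per-window polynomial least squares evaluated at the center."""
    x = np.asarray(x, dtype=float)
    n = x.size
    out = np.empty(n)
    for i in range(n):
        h = min(k // 2, i, n - 1 - i)
        t = np.arange(-h, h + 1, dtype=float)
        o = min(order, 2 * h)
        A = np.vander(t, o + 1, increasing=True)
        coef, *_ = np.linalg.lstsq(A, x[i - h:i + h + 1], rcond=None)
        out[i] = coef[0]
    return out


def ols_predict(X_train, y_train, X_test):
    """Ordinary least squares (with intercept) via the normal equations."""
    X_train = np.asarray(X_train, dtype=float)
    A = np.column_stack([np.ones(len(X_train)), X_train])
    beta, *_ = np.linalg.lstsq(A, np.asarray(y_train, dtype=float), rcond=None)
    At = np.column_stack([np.ones(len(X_test)), np.asarray(X_test, dtype=float)])
    return At @ beta
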
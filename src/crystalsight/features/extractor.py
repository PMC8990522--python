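"""Frame-to-feature-vector extraction.

`extract_all` evaluates a registry on a single frame; `FrameFeatureExtractor`
wraps the same machinery as a scikit-learn transformer so extraction can sit
inside pipelines (fit stores the optional background reference, transform
maps a sequence of frames to a (n_frames, n_features) matrix).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from ..frames import GrayFrame
from . import ops
from .registry import FeatureEntry, FeatureRegistry, default_registry

__all__ = ["extract_all", "FrameFeatureExtractor"]


def _evaluate_method(frame, method: str, params: dict) -> dict[str, float]:
    if method == "global_stats":
        return ops.global_stats(frame)
    if method == "hist_params":
        vals, _ = ops.histogram_params(frame, background=params.get("_background"))
        return vals
    if method == "brenner":
        return {"BREN": ops.gradient_focus(frame)["BREN"]}
    if method in ("tenengrad", "prewitt", "sobel", "laplacian"):
        g = ops.gradient_focus(frame)
        pick = {"tenengrad": ("TENG",), "prewitt": ("PRWM", "PRWV"),
                "sobel": ("SOBM", "SOBV"), "laplacian": ("LAPM", "LAPV")}[method]
        return {n: g[n] for n in pick}
    if method.startswith("wavelet_db6_l"):
        return ops.wavelet_features(frame, level=params["level"],
                                    wavelet=params.get("wavelet", "db6"))
    if method.startswith("range_"):
        return ops.range_features(frame, params["k"])
    if method.startswith("locvar_"):
        return ops.local_variance_features(frame, params["k"])
    if method.startswith("helm_"):
        return ops.helm_features(frame, params["k"])
    if method.startswith("rnggauss_"):
        return ops.range_gauss_features(frame, params["k"])
    if method == "gauss_grad":
        return ops.gauss_gradient_features(frame, params.get("sigma", 2.0))
    if method == "dog":
        return ops.dog_features(frame, params.get("sigma_lo", 2.0),
                                params.get("sigma_hi", 4.0))
    raise ValueError(f"unknown extraction method {method!r}")


def _extract(frame, entries: list[FeatureEntry], background) -> np.ndarray:
    # evaluate each distinct method once, then read out per-feature values
    cache: dict[str, dict[str, float]] = {}
    values = np.empty(len(entries))
    # gradient methods share one underlying computation
    grad_methods = {"brenner", "tenengrad", "prewitt", "sobel", "laplacian"}
    wanted_grad = [e for e in entries if e.method in grad_methods]
    if wanted_grad:
        g = ops.gradient_focus(frame)
        for m in grad_methods:
            cache[m] = g
    for i, e in enumerate(entries):
        if e.method not in cache:
            params = dict(e.params)
            if e.method == "hist_params":
                params["_background"] = background
            cache[e.method] = _evaluate_method(frame, e.method, params)
        v = cache[e.method][e.name]
        if not np.isfinite(v):
            raise ValueError(f"feature {e.name!r} evaluated to a non-finite value")
        values[i] = v
    return values


def extract_all(frame, registry: FeatureRegistry | None = None,
                background=None) -> dict[str, float]:
    """Evaluate every registry entry on one frame, in registry order.

    Returns a name -> value mapping with all values finite; raises if any
    feature evaluates to a non-finite number.
    """
    registry = registry if registry is not None else default_registry()
    vals = _extract(frame, list(registry), background)
    return dict(zip(registry.names, vals))


class FrameFeatureExtractor(TransformerMixin, BaseEstimator):
    """Scikit-learn style extractor mapping frames to feature matrices.

    Parameters
    ----------
    registry : FeatureRegistry, optional
        Feature catalog; defaults to the built-in 80-feature registry.
    feature_names : list of str, optional
        Restrict extraction to a subset of registry features (e.g. only
        HELM_5 for routine event detection). Order follows the registry.
    """

    def __init__(self, registry: FeatureRegistry | None = None,
                 feature_names: list[str] | None = None):
        self.registry = registry
        self.feature_names = feature_names

    def _entries(self) -> list[FeatureEntry]:
        reg = self.registry if self.registry is not None else default_registry()
        if self.feature_names is None:
            return list(reg)
        order = {n: i for i, n in enumerate(reg.names)}
        wanted = sorted(self.feature_names, key=order.__getitem__)
        return reg.subset(wanted)

    def fit(self, X=None, y=None, background=None):
        """Store the optional background reference frame.

        ``background`` anchors the HistSumBK / HistTailBK percentile cuts;
        without it those two features fall back to self-referenced cuts.
        """
        self.background_ = background
        self.entries_ = self._entries()
        self.feature_names_out_ = [e.name for e in self.entries_]
        return self

    def transform(self, X) -> np.ndarray:
        """Extract features for a sequence of frames -> (n_frames, n_feat)."""
        if not hasattr(self, "entries_"):
            self.fit()
        frames = [X] if isinstance(X, GrayFrame) or (
            isinstance(X, np.ndarray) and X.ndim == 2) else list(X)
        out = np.empty((len(frames), len(self.entries_)))
        for i, f in enumerate(frames):
            out[i] = _extract(f, self.entries_, self.background_)
        return out

    def get_feature_names_out(self, input_features=None):
        if not hasattr(self, "entries_"):
            self.fit()
        return np.asarray(self.feature_names_out_, dtype=object)
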
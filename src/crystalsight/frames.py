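"""Grayscale frame container used throughout the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GrayFrame"]


@dataclass(frozen=True)
class GrayFrame:
    """One 8-bit grayscale image with its acquisition metadata.

    Parameters
    ----------
    pixels : ndarray of uint8, shape (rows, cols)
        Row-major intensities, origin top-left.
    time_s : float
        Acquisition time relative to the start of the experiment.
    temperature_C : float
        Reactor temperature logged with the frame.
    """

    pixels: np.ndarray
    time_s: float = 0.0
    temperature_C: float = float("nan")

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 3 or px.shape[1] < 3:
            raise ValueError("frame must be a 2-D image of at least 3x3 pixels")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def as_float(self) -> np.ndarray:
        """Pixels as float64, still on the raw 0-255 scale."""
        return self.pixels.astype(np.float64)
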
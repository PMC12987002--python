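"""Sharpness and fidelity metrics for multi-focus fusion.

Two gradient conventions coexist on purpose and must not be merged:

* :func:`average_gradient` is the fusion-literature sharpness score
  ``mean sqrt((Gx^2 + Gy^2)/2)`` with *forward differences*, evaluated on the
  (H-1)x(W-1) interior.  It is used to rank fusion outputs.
* :func:`gradient_magnitude` is the per-pixel edge-strength map
  ``sqrt(Gx^2 + Gy^2)`` with *Sobel* operators (reflect-padded), used by the
  boundary-localization stage where noise robustness matters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["QualityScores", "average_gradient", "gradient_magnitude", "mse", "score_image"]


@dataclass(frozen=True)
class QualityScores:
    """Fusion-quality summary: sharpness plus optional reference error."""

    average_gradient: float
    mse_to_reference: float | None = None


def _as_float_image(image) -> np.ndarray:
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {arr.shape}")
    return arr


def average_gradient(image) -> float:
    """Average gradient (AG) sharpness score of a grayscale image.

    AG = mean over the (H-1)x(W-1) interior of sqrt((Gx^2 + Gy^2) / 2) with
    forward differences Gx, Gy.  A constant image scores exactly 0; a
    horizontal ramp with per-pixel step ``s`` scores ``s / sqrt(2)``.
    """
    arr = _as_float_image(image)
    h, w = arr.shape
    if h < 2 or w < 2:
        raise ValueError("average_gradient requires an image of at least 2x2 pixels")
    gx = arr[:-1, 1:] - arr[:-1, :-1]
    gy = arr[1:, :-1] - arr[:-1, :-1]
    return float(np.mean(np.sqrt((gx * gx + gy * gy) / 2.0)))


def gradient_magnitude(image) -> np.ndarray:
    """Per-pixel Sobel gradient magnitude, reflect-padded at the borders."""
    arr = _as_float_image(image)
    if arr.shape[0] < 3 or arr.shape[1] < 3:
        raise ValueError("gradient_magnitude requires an image of at least 3x3 pixels")
    gx = ndimage.sobel(arr, axis=1, mode="reflect")
    gy = ndimage.sobel(arr, axis=0, mode="reflect")
    return np.sqrt(gx * gx + gy * gy)


def mse(image, reference) -> float:
    """Mean squared error between two equally shaped grayscale images."""
    a = _as_float_image(image)
    b = _as_float_image(reference)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    d = a - b
    return float(np.mean(d * d))


def score_image(image, reference=None) -> QualityScores:
    """Compute :class:`QualityScores` for an image, optionally vs a reference."""
    ag = average_gradient(image)
    err = mse(image, reference) if reference is not None else None
    return QualityScores(average_gradient=ag, mse_to_reference=err)
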
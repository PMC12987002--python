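"""Classical Laplacian-pyramid multi-focus fusion.

Each focal plane is decomposed into a band-pass pyramid; at every band-pass
coefficient the fusion keeps the input with the maximum absolute response, so
the locally sharpest plane wins at every scale.  The fused pyramid is collapsed
back into a single all-in-focus composite.  This classical method is both the
baseline fusion engine and the distillation target for the neural fusion nets.

Numerical conventions (the underlying references leave them open):

* smoothing kernel: 5-tap binomial [1, 4, 6, 4, 1] / 16, reflect padding;
* down-sampling by taking every second sample (ceil-halving);
* up-sampling by normalized zero-insertion interpolation (smoothed samples
  divided by the smoothed sampling indicator), which preserves constants at
  the borders and makes ``collapse`` the exact inverse of ``build_laplacian``
  by construction;
* the coarse low-pass residual is fused by element-wise mean by default
  (``residual="mean"``) because literal max-abs selection on the residual
  biases overall brightness; ``residual="max-abs"`` is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["LaplacianPyramid", "build_laplacian", "collapse", "fuse_lp"]

_KERNEL = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


@dataclass
class LaplacianPyramid:
    """Band-pass levels (finest first) plus the coarsest low-pass residual."""

    band_levels: list = field(default_factory=list)
    residual: np.ndarray | None = None

    @property
    def n_levels(self) -> int:
        return len(self.band_levels) + 1

    def validate(self) -> None:
        if self.residual is None:
            raise ValueError("pyramid has no residual level")
        shapes = [lvl.shape for lvl in self.band_levels] + [self.residual.shape]
        for fine, coarse in zip(shapes, shapes[1:]):
            expected = (-(-fine[0] // 2), -(-fine[1] // 2))
            if coarse != expected:
                raise ValueError(
                    f"inconsistent pyramid: level of shape {fine} followed by "
                    f"{coarse}, expected {expected}"
                )


def _smooth(image: np.ndarray) -> np.ndarray:
    out = ndimage.correlate1d(image, _KERNEL, axis=0, mode="reflect")
    return ndimage.correlate1d(out, _KERNEL, axis=1, mode="reflect")


def _down(image: np.ndarray) -> np.ndarray:
    return _smooth(image)[::2, ::2]


def _up(image: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Zero-insertion upsample to ``shape`` with normalized interpolation.

    The smoothed zero-stuffed grid is divided by the smoothed sampling
    indicator, so a constant coarse level up-samples to exactly that constant
    everywhere, borders included."""
    out = np.zeros(shape, dtype=np.float64)
    out[::2, ::2] = image
    indicator = np.zeros(shape, dtype=np.float64)
    indicator[::2, ::2] = 1.0
    for axis in (0, 1):
        out = ndimage.correlate1d(out, _KERNEL, axis=axis, mode="reflect")
        indicator = ndimage.correlate1d(indicator, _KERNEL, axis=axis, mode="reflect")
    return out / indicator


def build_laplacian(image, n_levels: int) -> LaplacianPyramid:
    """Decompose ``image`` into ``n_levels - 1`` band levels plus a residual.

    Band level ``j`` is the difference between the Gaussian level ``j`` and the
    up-sampled Gaussian level ``j + 1``; the residual is the final low-pass.
    """
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {arr.shape}")
    if n_levels < 2:
        raise ValueError("n_levels must be at least 2 (one band level + residual)")
    if min(arr.shape) / 2 ** (n_levels - 1) < 4:
        raise ValueError(
            f"{n_levels} levels is too deep for a {arr.shape} image "
            "(coarsest level would fall below 4 pixels)"
        )
    bands = []
    current = arr
    for _ in range(n_levels - 1):
        coarser = _down(current)
        bands.append(current - _up(coarser, current.shape))
        current = coarser
    return LaplacianPyramid(band_levels=bands, residual=current)


def collapse(pyramid: LaplacianPyramid, clip: bool = True) -> np.ndarray:
    """Invert :func:`build_laplacian`; output clipped to [0, 1] by default."""
    pyramid.validate()
    current = pyramid.residual
    for band in reversed(pyramid.band_levels):
        current = band + _up(current, band.shape)
    return np.clip(current, 0.0, 1.0) if clip else current


def fuse_lp(stack, n_levels: int = 4, residual: str = "mean") -> np.ndarray:
    """Fuse a focal stack by per-coefficient max-abs selection.

    ``stack`` is a :class:`~embryofuse.phantom.FocalStack` or any iterable of
    equally shaped 2-D planes.  At every band-pass position the coefficient
    with the maximum absolute value across the planes is kept (ties resolved
    toward the lowest plane index); the low-pass residual is fused per the
    ``residual`` rule.  The fused pyramid is collapsed and clipped to [0, 1].
    """
    planes = [np.asarray(p, dtype=np.float64) for p in getattr(stack, "planes", stack)]
    if not planes:
        raise ValueError("empty stack")
    shape = planes[0].shape
    if any(p.shape != shape for p in planes):
        raise ValueError("all planes must share the same shape")
    if residual not in ("mean", "max-abs"):
        raise ValueError(f"unknown residual rule {residual!r}")

    pyramids = [build_laplacian(p, n_levels) for p in planes]
    fused_bands = []
    for j in range(n_levels - 1):
        coeffs = np.stack([pyr.band_levels[j] for pyr in pyramids])
        winner = np.argmax(np.abs(coeffs), axis=0)  # first max wins ties
        fused_bands.append(np.take_along_axis(coeffs, winner[None], axis=0)[0])
    residuals = np.stack([pyr.residual for pyr in pyramids])
    if residual == "mean":
        fused_residual = residuals.mean(axis=0)
    else:
        winner = np.argmax(np.abs(residuals), axis=0)
        fused_residual = np.take_along_axis(residuals, winner[None], axis=0)[0]
    return collapse(LaplacianPyramid(band_levels=fused_bands, residual=fused_residual))
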
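"""Embryo localization: coarse circular-object detection, radial boundary
refinement, and the standard 224x224 crop.

The coarse stage replaces a trained cascade detector with ring-template
matched filtering on the Sobel gradient-magnitude map: for a sweep of radii,
each pixel is scored by the mean edge strength along a circle of that radius
centered on it, and the best (center, radius) wins.  A hook accepts any
externally supplied detector with the same contract.

The fine stage casts ``n_rays`` equally spaced rays from the candidate
center, records the sub-pixel arg-max of the gradient magnitude along each
ray (parabolic interpolation around the peak), takes the median per-ray
radius as the boundary radius, re-centers on the centroid of the per-ray
edge points, and repeats once from the new center.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve
from skimage.transform import resize as _sk_resize

from embryofuse.metrics import gradient_magnitude

__all__ = [
    "NoDetectionError",
    "WeakEdgeError",
    "CandidateBox",
    "BoundaryEstimate",
    "coarse_detect",
    "radial_refine",
    "crop_resize",
    "locate_embryo",
]


class NoDetectionError(RuntimeError):
    """No circular object scored above the detection threshold."""


class WeakEdgeError(RuntimeError):
    """All radial gradient maxima fell below the edge floor."""


@dataclass(frozen=True)
class CandidateBox:
    center: tuple[float, float]  # (x, y), 0-based, x = column
    half_width: float
    score: float
    clipped: bool = False


@dataclass
class BoundaryEstimate:
    center: tuple[float, float]
    radius: float
    per_ray_radii: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_rays: int = 0

    def validate(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if len(self.per_ray_radii) != self.n_rays:
            raise ValueError("per_ray_radii length must equal n_rays")


def _ring_kernel(radius: float, width: float = 5.0) -> np.ndarray:
    half = int(np.ceil(radius + width))
    y, x = np.mgrid[-half:half + 1, -half:half + 1].astype(np.float64)
    ring = (np.abs(np.hypot(x, y) - radius) <= width / 2.0).astype(np.float64)
    return ring / ring.sum()


def _ring_support(field: np.ndarray, radius: float) -> np.ndarray:
    """Mean of ``field`` along a circle of ``radius`` around every pixel,
    normalized by the in-bounds fraction of the circle (so objects clipped by
    the image border are scored on their visible arc only)."""
    kernel = _ring_kernel(radius)
    num = fftconvolve(field, kernel, mode="same")
    den = fftconvolve(np.ones_like(field), kernel, mode="same")
    return num / np.maximum(den, 1e-9), den


def coarse_detect(image, r_min: float | None = None, r_max: float | None = None,
                  n_radii: int = 20, min_support: float = 0.5,
                  max_outside: float = 0.25) -> CandidateBox:
    """Find the best circular-object candidate by ring-matched filtering.

    The Sobel gradient magnitude of the blurred image is thresholded into an
    edge map; a candidate (center, radius) needs at least ``min_support`` of
    its visible circle on edges, at most ``max_outside`` edge support on a
    circle 22% larger (the outside of a real boundary is quiet background),
    and at least 20% of the circle inside the image.  Among candidates whose
    support is within 85% of the best, the largest radius wins — the zona
    pellucida is the outermost circular structure — so interior cell
    membranes are rejected.  Raises :class:`NoDetectionError` when no
    candidate qualifies (the "empty well" path).
    """
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2 or min(arr.shape) < 32:
        raise ValueError("coarse_detect needs a 2-D image of at least 32x32 pixels")
    h, w = arr.shape
    grad = gradient_magnitude(ndimage.gaussian_filter(arr, 2.0))
    floor = max(2.5 * float(np.median(grad)), 1e-8)
    edges = (grad > floor).astype(np.float64)
    if not edges.any():
        raise NoDetectionError("image has no gradient structure")

    if r_min is None:
        r_min = 0.15 * min(h, w)
    if r_max is None:
        r_max = 0.47 * min(h, w)
    candidates = []  # (radius, support, center)
    for radius in np.linspace(r_max, r_min, n_radii):
        support, in_bounds = _ring_support(edges, radius)
        outside, _ = _ring_support(edges, 1.22 * radius)
        mask = (support >= min_support) & (outside <= max_outside) & (in_bounds >= 0.2)
        if mask.any():
            masked = np.where(mask, support, -np.inf)
            idx = np.unravel_index(np.argmax(masked), masked.shape)
            candidates.append((float(radius), float(support[idx]),
                               (float(idx[1]), float(idx[0]))))
    if not candidates:
        raise NoDetectionError(
            f"no circular candidate with edge support >= {min_support} and "
            f"quiet exterior <= {max_outside}"
        )
    top = max(s for _, s, _ in candidates)
    radius, score, center = max(
        (c for c in candidates if c[1] >= 0.85 * top), key=lambda c: c[0]
    )

    cx, cy = center
    clipped = (cx - radius < 0 or cy - radius < 0 or cx + radius > w - 1
               or cy + radius > h - 1)
    if clipped:
        x0, x1 = max(0.0, cx - radius), min(w - 1.0, cx + radius)
        y0, y1 = max(0.0, cy - radius), min(h - 1.0, cy + radius)
        cx, cy = (x0 + x1) / 2.0, (y0 + y1) / 2.0
        radius = min(x1 - x0, y1 - y0) / 2.0
    return CandidateBox(center=(cx, cy), half_width=radius, score=score, clipped=clipped)


def _cast_rays(grad: np.ndarray, center: tuple[float, float], n_rays: int,
               r_min: float, r_max: float):
    """Sub-pixel arg-max radius and peak value of ``grad`` along each ray."""
    angles = np.linspace(0.0, 2.0 * np.pi, n_rays, endpoint=False)
    ts = np.arange(r_min, r_max, 0.5)
    cx, cy = center
    xs = cx + np.outer(np.cos(angles), ts)
    ys = cy + np.outer(np.sin(angles), ts)
    profiles = ndimage.map_coordinates(grad, [ys.ravel(), xs.ravel()],
                                       order=1, mode="nearest").reshape(n_rays, len(ts))
    peak_idx = np.argmax(profiles, axis=1)
    peaks = profiles[np.arange(n_rays), peak_idx]
    radii = ts[peak_idx].astype(np.float64)
    # parabolic interpolation around interior maxima for sub-pixel edges
    interior = (peak_idx > 0) & (peak_idx < len(ts) - 1)
    i = peak_idx[interior]
    rows = np.flatnonzero(interior)
    y0, y1, y2 = (profiles[rows, i - 1], profiles[rows, i], profiles[rows, i + 1])
    denom = y0 - 2.0 * y1 + y2
    shift = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / np.where(denom == 0, 1, denom), 0.0)
    radii[rows] += np.clip(shift, -1.0, 1.0) * 0.5
    return radii, peaks, angles


def radial_refine(image, init_center: tuple[float, float], n_rays: int = 180,
                  r_min: float = 4.0, r_max: float | None = None,
                  max_iter: int = 5) -> BoundaryEstimate:
    """Refine the embryo boundary by radial gradient search from a center guess.

    Each pass casts rays, re-centers on the centroid of the per-ray edge
    points, and repeats from the new center until the center moves less than
    0.3 px (at most ``max_iter`` passes)."""
    arr = np.asarray(image, dtype=np.float64)
    h, w = arr.shape
    cx, cy = init_center
    border = min(cx, cy, w - 1 - cx, h - 1 - cy)
    if r_max is None:
        r_max = border
    if n_rays < 8:
        raise ValueError("n_rays must be at least 8")
    if not r_min < r_max <= border + 1e-9:
        raise ValueError(
            f"need r_min < r_max <= distance to nearest border "
            f"({r_min=}, {r_max=}, border={border:.1f})"
        )
    grad = gradient_magnitude(ndimage.gaussian_filter(arr, 1.0))
    floor = max(3.0 * float(np.median(grad)), 1e-8)

    center = (float(cx), float(cy))
    radii = None
    for _ in range(max_iter):
        radii, peaks, angles = _cast_rays(grad, center, n_rays, r_min, r_max)
        if np.all(peaks < floor):
            raise WeakEdgeError("no radial gradient maximum exceeds the edge floor")
        strong = peaks >= floor
        ex = center[0] + radii[strong] * np.cos(angles[strong])
        ey = center[1] + radii[strong] * np.sin(angles[strong])
        new_center = (float(ex.mean()), float(ey.mean()))
        shift = np.hypot(new_center[0] - center[0], new_center[1] - center[1])
        center = new_center
        if shift < 0.3:
            break

    est = BoundaryEstimate(center=center, radius=float(np.median(radii)),
                           per_ray_radii=radii, n_rays=n_rays)
    est.validate()
    return est


def crop_resize(image, boundary: BoundaryEstimate, out_size: int = 224,
                margin: float = 0.1) -> np.ndarray:
    """Square crop of side ``2 * radius * (1 + margin)`` resized to ``out_size``.

    The crop is centered on the boundary center and edge-padded where it
    exceeds the image bounds; output values stay in [0, 1].
    """
    arr = np.asarray(image, dtype=np.float64)
    h, w = arr.shape
    side = max(int(round(2.0 * boundary.radius * (1.0 + margin))), 2)
    cx, cy = boundary.center
    x0 = int(round(cx - side / 2.0))
    y0 = int(round(cy - side / 2.0))
    pad_l = max(0, -x0)
    pad_t = max(0, -y0)
    pad_r = max(0, x0 + side - w)
    pad_b = max(0, y0 + side - h)
    if pad_l or pad_t or pad_r or pad_b:
        arr = np.pad(arr, ((pad_t, pad_b), (pad_l, pad_r)), mode="edge")
        x0 += pad_l
        y0 += pad_t
    crop = arr[y0:y0 + side, x0:x0 + side]
    if side == out_size:
        return crop.copy()
    out = _sk_resize(crop, (out_size, out_size), order=1, mode="edge",
                     anti_aliasing=side > out_size, preserve_range=True)
    return np.clip(out, 0.0, 1.0)


def locate_embryo(image, n_rays: int = 180, detector=None) -> BoundaryEstimate:
    """Coarse detection followed by radial refinement.

    ``detector`` may be any callable with the :func:`coarse_detect` contract
    (e.g. an externally trained cascade); the built-in matched filter is used
    by default.
    """
    box = (detector or coarse_detect)(image)
    arr = np.asarray(image)
    h, w = arr.shape
    cx, cy = box.center
    border = min(cx, cy, w - 1 - cx, h - 1 - cy)
    r_max = min(1.35 * box.half_width, border)
    r_min = min(0.75 * box.half_width, 0.8 * r_max)
    return radial_refine(image, box.center, n_rays=n_rays, r_min=r_min, r_max=r_max)
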
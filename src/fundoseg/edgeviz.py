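"""Five-stage Canny edge detection, dilation, and boundary overlays.

The detector is implemented stage by stage — noise reduction by Gaussian
blur, x/y gradient filtering (3x3 Sobel pair), gradient magnitude and
direction, directional non-maximum suppression, double thresholding into
strong/weak pixels, and edge tracking by hysteresis — because the staged
pipeline itself is what this package visualizes.  For cup/disc boundary
figures the detector runs on the predicted binary masks (one per
structure), and the thin edge is thickened by binary dilation before
being painted over the fundus image.

Thresholds are fractions of the maximum gradient magnitude.  Non-maximum
suppression keeps ties (>= comparison) so plateau edges survive;
hysteresis is a full connected-component closure (8-connectivity), so
the result does not depend on scan order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "CannyParams",
    "canny",
    "gaussian_smooth",
    "sobel_gradients",
    "non_max_suppression",
    "double_threshold",
    "hysteresis",
    "dilate",
    "overlay",
    "rgb_to_gray",
]

DISC_COLOR = (0, 255, 0)
CUP_COLOR = (255, 0, 0)


@dataclass(frozen=True)
class CannyParams:
    gaussian_sigma: float = 1.4
    low_threshold: float = 0.05  # fraction of max gradient magnitude
    high_threshold: float = 0.15

    def validate(self) -> None:
        if not (0 < self.low_threshold < self.high_threshold <= 1):
            raise ValueError("need 0 < low < high <= 1 (fractions of max magnitude)")
        if self.gaussian_sigma <= 0:
            raise ValueError("gaussian_sigma must be positive")


def rgb_to_gray(image: np.ndarray) -> np.ndarray:
    """ITU-R 601 luminance."""
    arr = np.asarray(image, dtype=np.float64)
    return arr[..., 0] * 0.299 + arr[..., 1] * 0.587 + arr[..., 2] * 0.114


def _gaussian_kernel1d(sigma: float) -> np.ndarray:
    radius = max(1, int(np.ceil(3.0 * sigma)))  # 3-sigma truncation
    xs = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-0.5 * (xs / sigma) ** 2)
    return k / k.sum()


def gaussian_smooth(image: np.ndarray, sigma: float) -> np.ndarray:
    """Separable Gaussian blur with a 3-sigma truncated kernel."""
    k = _gaussian_kernel1d(sigma)
    out = ndimage.convolve1d(np.asarray(image, dtype=np.float64), k, axis=0, mode="nearest")
    return ndimage.convolve1d(out, k, axis=1, mode="nearest")


_SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float64)
_SOBEL_Y = _SOBEL_X.T


def sobel_gradients(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Gradient magnitude and direction (radians) from the Sobel pair."""
    gx = ndimage.convolve(image, _SOBEL_X, mode="nearest")
    gy = ndimage.convolve(image, _SOBEL_Y, mode="nearest")
    return np.hypot(gx, gy), np.arctan2(gy, gx)


def non_max_suppression(magnitude: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Thin edges: keep a pixel only if its magnitude is >= both
    neighbors along the quantized gradient direction (4 bins).

    Ties are kept so constant-magnitude ridges are not erased.
    """
    magnitude = np.asarray(magnitude, dtype=np.float64)
    if magnitude.shape != np.shape(direction):
        raise ValueError("magnitude and direction shapes differ")
    # quantize direction to {0, 45, 90, 135} degrees
    angle = np.mod(np.degrees(direction), 180.0)
    bins = np.zeros(magnitude.shape, dtype=np.int8)
    bins[(angle >= 22.5) & (angle < 67.5)] = 1
    bins[(angle >= 67.5) & (angle < 112.5)] = 2
    bins[(angle >= 112.5) & (angle < 157.5)] = 3

    padded = np.pad(magnitude, 1, mode="constant")
    core = padded[1:-1, 1:-1]

    # neighbor offsets along the gradient direction, per bin:
    # bin 0: horizontal gradient -> compare left/right (j-1, j+1)
    # bin 1: 45 deg -> (i-1, j+1) and (i+1, j-1)
    # bin 2: vertical gradient -> compare up/down (i-1, i+1)
    # bin 3: 135 deg -> (i-1, j-1) and (i+1, j+1)
    offsets = {
        0: ((0, -1), (0, 1)),
        1: ((-1, 1), (1, -1)),
        2: ((-1, 0), (1, 0)),
        3: ((-1, -1), (1, 1)),
    }
    keep = np.zeros(magnitude.shape, dtype=bool)
    for b, ((di1, dj1), (di2, dj2)) in offsets.items():
        n1 = padded[1 + di1 : padded.shape[0] - 1 + di1, 1 + dj1 : padded.shape[1] - 1 + dj1]
        n2 = padded[1 + di2 : padded.shape[0] - 1 + di2, 1 + dj2 : padded.shape[1] - 1 + dj2]
        sel = bins == b
        keep[sel] = (core[sel] >= n1[sel]) & (core[sel] >= n2[sel])
    return np.where(keep, magnitude, 0.0)


def double_threshold(suppressed: np.ndarray, low: float, high: float
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Categorize pixels into strong (>= high) and weak ([low, high))
    using thresholds relative to the maximum suppressed magnitude."""
    peak = suppressed.max()
    # guard against float residue on (near-)constant images
    if peak <= 1e-8 * max(1.0, float(np.abs(suppressed).max())):
        empty = np.zeros(suppressed.shape, dtype=bool)
        return empty, empty.copy()
    strong = suppressed >= high * peak
    weak = (suppressed >= low * peak) & ~strong
    return strong, weak


def hysteresis(strong: np.ndarray, weak: np.ndarray) -> np.ndarray:
    """Keep strong pixels plus weak pixels 8-connected to a strong pixel
    through chains of weak/strong pixels (full flood-fill closure)."""
    strong = np.asarray(strong, dtype=bool)
    weak = np.asarray(weak, dtype=bool)
    if np.any(strong & weak):
        raise ValueError("strong and weak sets must be disjoint")
    candidates = strong | weak
    labels, n = ndimage.label(candidates, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return np.zeros_like(strong)
    keep = np.zeros(n + 1, dtype=bool)
    keep[np.unique(labels[strong])] = True
    keep[0] = False
    return keep[labels]


def canny(image: np.ndarray, params: CannyParams | None = None) -> np.ndarray:
    """Run the five-stage pipeline on a single-channel image.

    Binary masks may be passed directly (cast to float); RGB input must
    be converted with :func:`rgb_to_gray` first.
    """
    params = params or CannyParams()
    params.validate()
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("canny expects a single-channel image; convert RGB with rgb_to_gray")
    if not np.isfinite(arr).all():
        raise ValueError("input contains non-finite pixels")
    smoothed = gaussian_smooth(arr, params.gaussian_sigma)
    magnitude, direction = sobel_gradients(smoothed)
    suppressed = non_max_suppression(magnitude, direction)
    strong, weak = double_threshold(suppressed, params.low_threshold, params.high_threshold)
    return hysteresis(strong, weak)


def dilate(mask: np.ndarray, kernel_size: int = 3, iterations: int = 1) -> np.ndarray:
    """Binary dilation with a square structuring element: each output
    pixel is the neighborhood maximum, so the foreground only grows."""
    if kernel_size < 1 or kernel_size % 2 == 0:
        raise ValueError("kernel_size must be an odd integer >= 1")
    out = np.asarray(mask, dtype=bool)
    structure = np.ones((kernel_size, kernel_size), dtype=bool)
    for _ in range(iterations):
        out = ndimage.binary_dilation(out, structure=structure)
    return out


def overlay(original: np.ndarray, disc_edges: np.ndarray, cup_edges: np.ndarray,
            disc_color=DISC_COLOR, cup_color=CUP_COLOR) -> np.ndarray:
    """Paint edge pixels over the image; cup color wins on overlap."""
    image = np.asarray(original, dtype=np.uint8).copy()
    disc_edges = np.asarray(disc_edges, dtype=bool)
    cup_edges = np.asarray(cup_edges, dtype=bool)
    if disc_edges.shape != image.shape[:2] or cup_edges.shape != image.shape[:2]:
        raise ValueError("edge maps must match the image resolution (resize first)")
    image[disc_edges] = disc_color
    image[cup_edges] = cup_color
    return image
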
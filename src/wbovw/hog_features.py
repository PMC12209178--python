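"""Per-keypoint histogram-of-oriented-gradients descriptors.

Gradients are unscaled central differences, gx = I(x+1, y) − I(x−1, y) and
gy = I(x, y+1) − I(x, y−1) (one-sided at borders), with magnitude
G = sqrt(gx² + gy²) and unsigned orientation φ = atan2(gy, gx) folded into
[0°, 180°).  The square window around a keypoint — side proportional to the
keypoint scale — is split into a 4×4 grid; in each cell the gradient
magnitude is accumulated into nine 20°-wide orientation bins (hard
assignment: all mass to the single bin containing φ), each 9-vector is
L2-normalized with a small ε, and the 16 cell histograms are concatenated
into a 144-dimensional descriptor.

Descriptors are invariant to adding a constant intensity (gradients are
unchanged) and, up to ε effects, to multiplying the image by a positive
constant (per-cell normalization).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging_io import GrayImage
from .scale_space import KeyPoint

__all__ = [
    "GradientField",
    "HogParams",
    "WindowOutOfBounds",
    "compute_gradients",
    "subregion_histogram",
    "keypoint_descriptor",
    "describe_image",
]


class WindowOutOfBounds(ValueError):
    """Descriptor window crosses the image border or the ROI mask."""


@dataclass(frozen=True)
class GradientField:
    """Signed difference gradients with magnitude and folded orientation."""

    gx: np.ndarray
    gy: np.ndarray
    magnitude: np.ndarray
    orientation: np.ndarray  # degrees in [0, 180)


@dataclass(frozen=True)
class HogParams:
    """Descriptor geometry: 4×4 cells × 9 unsigned-orientation bins = 144.

    The window side is max(16, round(window_scale_multiplier · σ)) rounded
    up to a multiple of ``grid`` so cells tile it exactly.
    """

    window_scale_multiplier: float = 6.0
    grid: int = 4
    n_bins: int = 9
    norm_epsilon: float = 1e-6

    @property
    def descriptor_length(self) -> int:
        return self.grid * self.grid * self.n_bins

    def window_side(self, sigma: float) -> int:
        side = max(16, int(round(self.window_scale_multiplier * sigma)))
        if side % self.grid:
            side += self.grid - side % self.grid
        return side


def compute_gradients(img: GrayImage | np.ndarray) -> GradientField:
    """Central-difference gradients; one-sided differences on the borders."""
    p = img.pixels if isinstance(img, GrayImage) else np.asarray(img, dtype=np.float64)
    if min(p.shape) < 3:
        raise ValueError("image must be at least 3 pixels on each side")
    gx = np.empty_like(p)
    gx[:, 1:-1] = p[:, 2:] - p[:, :-2]
    gx[:, 0] = p[:, 1] - p[:, 0]
    gx[:, -1] = p[:, -1] - p[:, -2]
    gy = np.empty_like(p)
    gy[1:-1, :] = p[2:, :] - p[:-2, :]
    gy[0, :] = p[1, :] - p[0, :]
    gy[-1, :] = p[-1, :] - p[-2, :]
    magnitude = np.hypot(gx, gy)
    orientation = np.degrees(np.arctan2(gy, gx)) % 180.0
    return GradientField(gx=gx, gy=gy, magnitude=magnitude, orientation=orientation)


def _normalize(v: np.ndarray, eps: float) -> np.ndarray:
    return v / np.sqrt(np.dot(v, v) + eps * eps)


def subregion_histogram(
    field: GradientField,
    region: tuple[slice, slice],
    p: HogParams = HogParams(),
) -> np.ndarray:
    """Hard-binned, L2-normalized 9-bin orientation histogram of a window.

    Each pixel's full magnitude goes to the single 20° bin containing its
    orientation; the histogram is then normalized as v / sqrt(‖v‖² + ε²),
    so a zero-gradient region stays the zero vector.
    """
    mag = field.magnitude[region]
    ori = field.orientation[region]
    bin_width = 180.0 / p.n_bins
    idx = np.minimum((ori / bin_width).astype(np.intp), p.n_bins - 1)
    hist = np.bincount(idx.ravel(), weights=mag.ravel(), minlength=p.n_bins)
    return _normalize(hist, p.norm_epsilon)


def keypoint_descriptor(
    field: GradientField,
    kp: KeyPoint,
    p: HogParams = HogParams(),
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Concatenate the 4×4 grid of cell histograms around one keypoint.

    Raises :class:`WindowOutOfBounds` when the scale-dependent window
    crosses the image border or covers a masked-out pixel; the caller drops
    such keypoints.
    """
    side = p.window_side(kp.sigma)
    half = side // 2
    h, w = field.magnitude.shape
    x0, y0 = kp.x - half, kp.y - half
    x1, y1 = x0 + side, y0 + side
    if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
        raise WindowOutOfBounds(f"window [{x0}:{x1}]x[{y0}:{y1}] exceeds {w}x{h} image")
    if mask is not None and not np.all(mask[y0:y1, x0:x1]):
        raise WindowOutOfBounds("window covers masked-out pixels")
    cell = side // p.grid
    blocks = []
    for gy_i in range(p.grid):
        for gx_i in range(p.grid):
            region = (
                slice(y0 + gy_i * cell, y0 + (gy_i + 1) * cell),
                slice(x0 + gx_i * cell, x0 + (gx_i + 1) * cell),
            )
            blocks.append(subregion_histogram(field, region, p))
    return np.concatenate(blocks)


def describe_image(
    img: GrayImage,
    kps: list[KeyPoint],
    p: HogParams = HogParams(),
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Descriptor matrix: one 144-row per keypoint that fits in bounds.

    Keypoint order is preserved; keypoints whose window leaves the image or
    the ROI mask are silently dropped, so the row count may be smaller than
    ``len(kps)`` (possibly zero).
    """
    field = compute_gradients(img)
    rows = []
    for kp in kps:
        try:
            rows.append(keypoint_descriptor(field, kp, p, mask=mask))
        except WindowOutOfBounds:
            continue
    if not rows:
        return np.zeros((0, p.descriptor_length))
    return np.vstack(rows)
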
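"""Gaussian scale space, difference-of-Gaussians stacks, and keypoints.

The detector builds a multi-octave Gaussian pyramid L(x, y, σ), subtracts
adjacent levels to get the DoG stack D(x, y, σ) = L(x, y, kσ) − L(x, y, σ)
with k = 2^(1/s), and marks a voxel as a keypoint when its D value is a
strict extremum over its 26 scale-space neighbours (8 in-plane plus 9 in
each adjacent level) and exceeds a contrast threshold in magnitude.

Positions are integer pixels (no sub-pixel refinement) mapped back to
base-image resolution, and there is no edge-response rejection — the only
pruning beyond the extremum test is the contrast threshold and, in
:func:`detect_keypoints`, removal of keypoints whose descriptor window
would cross the image border or the ROI mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imaging_io import GrayImage

__all__ = [
    "ScaleSpaceParams",
    "GaussianPyramid",
    "DogStack",
    "KeyPoint",
    "gaussian_filter_image",
    "build_scale_space",
    "build_dog",
    "detect_extrema",
    "detect_keypoints",
]


@dataclass(frozen=True)
class ScaleSpaceParams:
    """Scale-space construction parameters.

    ``intervals_per_octave`` (s) fixes the scale factor k = 2^(1/s); each
    octave holds s+3 Gaussian levels with σ_i = σ0·k^i so the DoG stack has
    s+2 levels and s interior levels usable for extremum detection.
    """

    n_octaves: int = 4
    intervals_per_octave: int = 3
    base_sigma: float = 1.6
    contrast_threshold: float = 0.01

    def __post_init__(self) -> None:
        if self.base_sigma <= 0:
            raise ValueError("base_sigma must be > 0")
        if self.intervals_per_octave < 1 or self.n_octaves < 1:
            raise ValueError("octave and interval counts must be >= 1")
        if self.contrast_threshold < 0:
            raise ValueError("contrast_threshold must be >= 0")

    @property
    def k(self) -> float:
        return 2.0 ** (1.0 / self.intervals_per_octave)


@dataclass(frozen=True)
class GaussianPyramid:
    """Per octave: a (levels, H, W) array of smoothed images and their σ.

    ``sigmas[o][i]`` is the absolute scale of ``octaves[o][i]`` in
    base-image units (i.e. already multiplied by 2^o).
    """

    octaves: list[np.ndarray]
    sigmas: list[np.ndarray]


@dataclass(frozen=True)
class DogStack:
    """Per octave: a (levels−1, H, W) stack of adjacent-level differences."""

    octaves: list[np.ndarray]
    sigmas: list[np.ndarray]  # σ of the lower level of each difference


@dataclass(frozen=True)
class KeyPoint:
    """A scale-space extremum at base-image pixel coordinates."""

    x: int
    y: int
    octave: int
    level: int
    sigma: float
    response: float


def gaussian_filter_image(img: GrayImage | np.ndarray, sigma: float) -> np.ndarray:
    """Smooth with a normalized Gaussian kernel of half-width ⌈3σ⌉.

    The kernel is the discretely sampled isotropic Gaussian, normalized to
    unit sum, applied separably with reflect padding; a constant image is
    therefore reproduced exactly.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    p = img.pixels if isinstance(img, GrayImage) else np.asarray(img, dtype=np.float64)
    radius = math.ceil(3.0 * sigma)
    return ndimage.gaussian_filter(p, sigma=sigma, mode="reflect", radius=radius)


def max_feasible_octaves(shape: tuple[int, int]) -> int:
    """Largest octave count n with min(H, W) ≥ 2^n · 8."""
    n = 0
    while min(shape) >= 2 ** (n + 1) * 8:
        n += 1
    return n


def build_scale_space(img: GrayImage | np.ndarray, p: ScaleSpaceParams) -> GaussianPyramid:
    """Build the multi-octave Gaussian pyramid.

    Each octave smooths its base image directly to σ_i = σ0·k^i for
    i = 0..s+2; the next octave's base is the level at σ = 2σ0 decimated by
    taking every second pixel.
    """
    base = img.pixels if isinstance(img, GrayImage) else np.asarray(img, dtype=np.float64)
    feasible = max_feasible_octaves(base.shape)
    if feasible < p.n_octaves:
        raise ValueError(
            f"image of shape {base.shape} supports at most {feasible} octaves, "
            f"requested {p.n_octaves}"
        )
    s = p.intervals_per_octave
    n_levels = s + 3
    octaves: list[np.ndarray] = []
    sigmas: list[np.ndarray] = []
    for o in range(p.n_octaves):
        rel_sigmas = p.base_sigma * p.k ** np.arange(n_levels)
        levels = np.stack([gaussian_filter_image(base, sg) for sg in rel_sigmas])
        octaves.append(levels)
        sigmas.append(rel_sigmas * 2.0**o)
        base = levels[s][::2, ::2]  # level with σ = 2σ0 seeds the next octave
    return GaussianPyramid(octaves=octaves, sigmas=sigmas)


def build_dog(pyr: GaussianPyramid) -> DogStack:
    """Difference adjacent Gaussian levels: D_i = L_{i+1} − L_i."""
    octs = []
    sigs = []
    for levels, sg in zip(pyr.octaves, pyr.sigmas):
        if levels.shape[0] < 2:
            raise ValueError("each octave needs at least 2 Gaussian levels")
        octs.append(levels[1:] - levels[:-1])
        sigs.append(sg[:-1])
    return DogStack(octaves=octs, sigmas=sigs)


def detect_extrema(dog: DogStack, contrast_threshold: float) -> list[KeyPoint]:
    """Find strict 26-neighbour extrema with |D| ≥ contrast_threshold.

    Only interior voxels qualify: levels with a neighbour above and below,
    and pixels away from the spatial border.  Ties with any neighbour are
    rejected (strict comparison), so plateaus yield no keypoints.
    Coordinates are mapped to base-image resolution via 2^octave.
    """
    footprint = np.ones((3, 3, 3), dtype=bool)
    footprint[1, 1, 1] = False
    keypoints: list[KeyPoint] = []
    for o, stack in enumerate(dog.octaves):
        if stack.shape[0] < 3:
            raise ValueError("extremum detection needs >= 3 DoG levels per octave")
        neigh_max = ndimage.maximum_filter(stack, footprint=footprint, mode="constant", cval=-np.inf)
        neigh_min = ndimage.minimum_filter(stack, footprint=footprint, mode="constant", cval=np.inf)
        is_ext = ((stack > neigh_max) | (stack < neigh_min)) & (
            np.abs(stack) >= contrast_threshold
        )
        is_ext[0, :, :] = False
        is_ext[-1, :, :] = False
        is_ext[:, 0, :] = False
        is_ext[:, -1, :] = False
        is_ext[:, :, 0] = False
        is_ext[:, :, -1] = False
        scale = 2**o
        for lv, yy, xx in zip(*np.nonzero(is_ext)):
            keypoints.append(
                KeyPoint(
                    x=int(xx) * scale,
                    y=int(yy) * scale,
                    octave=o,
                    level=int(lv),
                    sigma=float(dog.sigmas[o][lv]),
                    response=float(stack[lv, yy, xx]),
                )
            )
    return keypoints


def detect_keypoints(
    img: GrayImage,
    p: ScaleSpaceParams,
    mask: np.ndarray | None = None,
    window_side_fn=None,
) -> list[KeyPoint]:
    """Full detector: scale space → DoG → strict 26-neighbour extrema.

    When ``window_side_fn`` (σ → descriptor window side in px) is given,
    keypoints whose window would cross the image border, or cover any
    masked-out pixel of ``mask``, are dropped so descriptors never see
    padding or out-of-ROI content.  An empty result is valid.
    """
    pyr = build_scale_space(img, p)
    dog = build_dog(pyr)
    kps = detect_extrema(dog, p.contrast_threshold)
    if window_side_fn is None:
        return kps
    h, w = img.pixels.shape
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        bad = ~mask
        # integral image of masked-out pixels for O(1) window queries
        bad_cum = np.zeros((h + 1, w + 1), dtype=np.int64)
        bad_cum[1:, 1:] = np.cumsum(np.cumsum(bad, axis=0), axis=1)
    kept = []
    for kp in kps:
        side = window_side_fn(kp.sigma)
        half = side // 2
        x0, y0 = kp.x - half, kp.y - half
        x1, y1 = x0 + side, y0 + side
        if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
            continue
        if mask is not None:
            n_bad = (
                bad_cum[y1, x1] - bad_cum[y0, x1] - bad_cum[y1, x0] + bad_cum[y0, x0]
            )
            if n_bad > 0:
                continue
        kept.append(kp)
    return kept
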
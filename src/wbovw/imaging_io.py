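"""Image and annotation I/O, ROI extraction, preprocessing and augmentation.

All images are handled as :class:`GrayImage`: a 2-D float array with
intensities in [0, 1], indexed as I(x, y) with x the column and y the row
(0-based).  Region-of-interest (ROI) annotations are circles given in pixel
coordinates; the circular placental patch is cropped to a square with a
companion boolean mask so downstream feature extraction can ignore the
corners and any padding.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage import exposure, restoration, transform

__all__ = [
    "GrayImage",
    "RoiAnnotation",
    "RoiPatch",
    "AugmentConfig",
    "ManifestFormatError",
    "load_image",
    "load_manifest",
    "extract_roi",
    "denoise_wavelet",
    "equalize_hist",
    "augment",
    "augment_with_mask",
]

LABEL_MAP = {"normal": 0, "fgr": 1, "0": 0, "1": 1}

MANIFEST_COLUMNS = ("image_id", "center_x", "center_y", "radius", "label")


class ManifestFormatError(ValueError):
    """Raised when an annotation manifest is malformed."""


@dataclass(frozen=True)
class GrayImage:
    """A grayscale image with intensities in [0, 1].

    Parameters
    ----------
    pixels : ndarray of shape (height, width)
        Row-major intensity array; element ``pixels[y, x]`` is I(x, y).
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels, dtype=np.float64)
        if p.ndim != 2 or p.shape[0] < 1 or p.shape[1] < 1:
            raise ValueError("GrayImage requires a non-empty 2-D array")
        if not np.all(np.isfinite(p)):
            raise ValueError("GrayImage pixels must be finite")
        if p.min() < 0.0 or p.max() > 1.0:
            raise ValueError("GrayImage pixels must lie in [0, 1]")
        object.__setattr__(self, "pixels", p)

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "GrayImage":
        """Build from a raw array, rescaling integer dtypes to [0, 1]."""
        arr = np.asarray(arr)
        if np.issubdtype(arr.dtype, np.integer):
            info = np.iinfo(arr.dtype)
            arr = arr.astype(np.float64) / float(info.max)
        else:
            arr = np.clip(arr.astype(np.float64), 0.0, 1.0)
        return cls(arr)


@dataclass(frozen=True)
class RoiAnnotation:
    """A circular ROI on one image plus its binary label (0 normal, 1 FGR)."""

    image_id: str
    center_x: float
    center_y: float
    radius: float
    label: int

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"radius must be > 0, got {self.radius}")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")


@dataclass(frozen=True)
class RoiPatch:
    """Square crop around a circular ROI with an in-circle validity mask."""

    image: GrayImage
    mask: np.ndarray  # bool, same shape; True inside circle and source image
    annotation: RoiAnnotation


@dataclass(frozen=True)
class AugmentConfig:
    """Texture-preserving augmentation: brightness, contrast, rotation, crop.

    No scaling/affine/shear is applied — those would distort the granular
    texture primitives the classifier relies on.
    """

    brightness_delta_range: float = 0.1
    contrast_factor_range: tuple[float, float] = (0.9, 1.1)
    rotation_range_deg: float = 15.0
    crop_fraction: float = 0.9
    n_augments_per_image: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.contrast_factor_range
        if lo > hi:
            raise ValueError("contrast_factor_range must be ordered (lo, hi)")
        if not (0.0 < self.crop_fraction <= 1.0):
            raise ValueError("crop_fraction must lie in (0, 1]")
        if self.brightness_delta_range < 0 or self.rotation_range_deg < 0:
            raise ValueError("ranges must be non-negative")


def _parse_label(raw) -> int:
    key = str(raw).strip().lower()
    if key not in LABEL_MAP:
        raise ValueError(
            f"unknown label {raw!r}: expected one of 'normal', 'fgr', 0, 1"
        )
    return LABEL_MAP[key]


def load_manifest(path: str | Path) -> list[RoiAnnotation]:
    """Read an annotation manifest (CSV or JSON array) into annotations.

    The CSV dialect has header ``image_id,center_x,center_y,radius,label``;
    the JSON form is an array of objects with the same fields.  Labels may be
    the strings ``normal``/``fgr`` or the integers 0/1.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
        if not records:
            return []
        frame = pd.DataFrame.from_records(records)
    else:
        frame = pd.read_csv(path, dtype={"image_id": str})
    for col in MANIFEST_COLUMNS:
        if col not in frame.columns:
            raise ManifestFormatError(f"manifest is missing required column {col!r}")
    annotations = []
    for row in frame.itertuples(index=False):
        annotations.append(
            RoiAnnotation(
                image_id=str(row.image_id),
                center_x=float(row.center_x),
                center_y=float(row.center_y),
                radius=float(row.radius),
                label=_parse_label(row.label),
            )
        )
    return annotations


def load_image(path: str | Path) -> GrayImage:
    """Load an 8- or 16-bit grayscale PNG/TIFF, rescaled to [0, 1]."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        # collapse trivially replicated channels; true color input is rejected
        if np.all(arr[..., :1] == arr[..., : arr.shape[-1]]):
            arr = arr[..., 0]
        else:
            raise ValueError(f"{path}: expected a grayscale image, got color")
    return GrayImage.from_array(arr)


def extract_roi(img: GrayImage, ann: RoiAnnotation) -> RoiPatch:
    """Crop the (2r+1)-square around the ROI circle, masking the corners.

    Pixels outside the inscribed circle (or outside the source image, when
    the circle overhangs a border) are set to 0 and marked False in the mask.
    """
    r = int(round(ann.radius))
    cx, cy = int(round(ann.center_x)), int(round(ann.center_y))
    side = 2 * r + 1
    if cx + r < 0 or cy + r < 0 or cx - r >= img.width or cy - r >= img.height:
        raise ValueError(f"ROI circle for {ann.image_id} lies outside the image")
    crop = np.zeros((side, side), dtype=np.float64)
    inside_src = np.zeros((side, side), dtype=bool)
    x0, y0 = cx - r, cy - r
    sx0, sy0 = max(0, x0), max(0, y0)
    sx1, sy1 = min(img.width, x0 + side), min(img.height, y0 + side)
    crop[sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0] = img.pixels[sy0:sy1, sx0:sx1]
    inside_src[sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0] = True
    yy, xx = np.mgrid[0:side, 0:side]
    in_circle = (xx - r) ** 2 + (yy - r) ** 2 <= r**2
    mask = in_circle & inside_src
    crop[~mask] = 0.0
    return RoiPatch(image=GrayImage(crop), mask=mask, annotation=ann)


def denoise_wavelet(img: GrayImage) -> GrayImage:
    """Suppress speckle by soft-threshold wavelet shrinkage.

    A 2-level biorthogonal decomposition with the universal (VisuShrink)
    threshold, the noise scale estimated from the finest-level detail
    coefficients.  Deterministic; output clipped back to [0, 1].
    """
    sigma = restoration.estimate_sigma(img.pixels)
    with warnings.catch_warnings():
        # the universal threshold is derived for orthogonal bases; applying
        # it with a biorthogonal pair is a deliberate, documented choice
        warnings.simplefilter("ignore", UserWarning)
        out = restoration.denoise_wavelet(
            img.pixels,
            sigma=sigma,
            wavelet="bior2.2",
            mode="soft",
            method="VisuShrink",
            wavelet_levels=2,
            rescale_sigma=True,
        )
    return GrayImage(np.clip(out, 0.0, 1.0))


def equalize_hist(img: GrayImage, mask: np.ndarray) -> GrayImage:
    """Histogram-equalize using the intensity CDF of masked-in pixels only.

    The mapping is the (monotone) cumulative histogram over 256 bins, so the
    rank order of pixel values is preserved.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.pixels.shape:
        raise ValueError("mask shape must match image shape")
    if not mask.any():
        raise ValueError("mask selects no pixels")
    out = exposure.equalize_hist(img.pixels, nbins=256, mask=mask)
    return GrayImage(np.clip(out, 0.0, 1.0))


def _apply_one_augment(
    p: np.ndarray,
    rng: np.random.Generator,
    cfg: AugmentConfig,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    delta = rng.uniform(-cfg.brightness_delta_range, cfg.brightness_delta_range)
    lo, hi = cfg.contrast_factor_range
    factor = rng.uniform(lo, hi)
    theta = rng.uniform(-cfg.rotation_range_deg, cfg.rotation_range_deg)
    out = p.copy()
    m_out = None if mask is None else mask.copy()
    if factor != 1.0:
        m = out.mean()
        out = (out - m) * factor + m
    if delta != 0.0:
        out = out + delta
    out = np.clip(out, 0.0, 1.0)
    if theta != 0.0:
        out = transform.rotate(out, theta, order=1, mode="edge", preserve_range=True)
        out = np.clip(out, 0.0, 1.0)
        if m_out is not None:
            m_out = (
                transform.rotate(
                    m_out.astype(np.float64), theta, order=0, mode="constant", cval=0.0
                )
                > 0.5
            )
    if cfg.crop_fraction < 1.0:
        h, w = out.shape
        ch = max(1, int(round(h * np.sqrt(cfg.crop_fraction))))
        cw = max(1, int(round(w * np.sqrt(cfg.crop_fraction))))
        oy = rng.integers(0, h - ch + 1)
        ox = rng.integers(0, w - cw + 1)
        out = out[oy : oy + ch, ox : ox + cw]
        out = transform.resize(out, (h, w), order=1, preserve_range=True, anti_aliasing=False)
        out = np.clip(out, 0.0, 1.0)
        if m_out is not None:
            m_out = m_out[oy : oy + ch, ox : ox + cw]
            m_out = (
                transform.resize(
                    m_out.astype(np.float64), (h, w), order=0, preserve_range=True,
                    anti_aliasing=False,
                )
                > 0.5
            )
    return out, m_out


def augment(img: GrayImage, cfg: AugmentConfig, rng: np.random.Generator) -> list[GrayImage]:
    """Generate ``cfg.n_augments_per_image`` perturbed copies of ``img``.

    Each copy applies, in order: contrast scaling about the image mean,
    a brightness shift, a rotation, and a random crop resized back to the
    original shape.  With a degenerate config (zero ranges, crop 1.0) the
    output equals the input exactly.  Reproducible for a given ``rng`` state.
    """
    return [
        GrayImage(_apply_one_augment(img.pixels, rng, cfg)[0])
        for _ in range(cfg.n_augments_per_image)
    ]


def augment_with_mask(
    patch: RoiPatch, cfg: AugmentConfig, rng: np.random.Generator
) -> list[tuple[GrayImage, np.ndarray]]:
    """Augment an ROI patch, carrying its validity mask through the
    geometric transforms (nearest-neighbour, photometric ops skip it)."""
    out = []
    for _ in range(cfg.n_augments_per_image):
        p, m = _apply_one_augment(patch.image.pixels, rng, cfg, mask=patch.mask)
        out.append((GrayImage(p), m))
    return out
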
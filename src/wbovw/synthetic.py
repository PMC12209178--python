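"""Synthetic ultrasound-like texture images for the two placental classes.

The generator emulates the texture contrast the classifier targets:
*normal* placentas show dot-like granular texture, modeled as isotropic
Gaussian-profiled blobs, while *FGR* placentas show short rod-like
texture, modeled as anisotropic Gaussian rods at random orientations.
Primitives are scattered uniformly inside a circular region of interest on
a uniform background and degraded by multiplicative speckle,
I·(1 + σ·η) with η standard normal per pixel — the granular noise
characteristic of ultrasound.

Every level (dataset, image, noise) is seeded, so regeneration is
byte-identical.  This is a texture phantom, not a physical ultrasound
simulation: there is no point-spread function, attenuation, or shadowing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .imaging_io import GrayImage

__all__ = ["SyntheticSpec", "render_texture", "apply_speckle", "generate_dataset"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Geometry, contrast, and noise of one synthetic placental image.

    Defaults mimic a screen-scale placental patch: a 256×256 frame, a
    100-px-radius circular ROI, and 150 texture primitives — 2-px dots for
    the normal class, 8×2-px rods for FGR.  ``rod_angle_jitter`` spreads
    rod orientations around a per-image random base angle, keeping local
    anisotropy while the global orientation distribution stays broad.
    """

    label: int  # 0 normal (dots), 1 fgr (rods)
    image_size: int = 256
    roi_radius: int = 100
    n_primitives: int = 150
    dot_radius: float = 2.0
    rod_length: float = 8.0
    rod_width: float = 2.0
    rod_angle_jitter: float = 90.0
    primitive_contrast: float = 0.35
    speckle_sigma: float = 0.15
    background_level: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        if self.speckle_sigma < 0:
            raise ValueError("speckle_sigma must be >= 0")
        extent = max(self.dot_radius, self.rod_length)
        if 3 * extent >= self.roi_radius:
            raise ValueError("primitives do not fit inside the ROI")
        if 2 * self.roi_radius >= self.image_size:
            raise ValueError("ROI must fit inside the image")


def _add_blob(
    canvas: np.ndarray,
    cx: float,
    cy: float,
    sigma_long: float,
    sigma_short: float,
    angle_deg: float,
    amplitude: float,
) -> None:
    """Accumulate one (possibly anisotropic) Gaussian profile in place."""
    extent = int(math.ceil(3.0 * sigma_long))
    h, w = canvas.shape
    x0, x1 = max(0, int(cx) - extent), min(w, int(cx) + extent + 1)
    y0, y1 = max(0, int(cy) - extent), min(h, int(cy) + extent + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - cx, yy - cy
    t = math.radians(angle_deg)
    u = dx * math.cos(t) + dy * math.sin(t)  # along the rod axis
    v = -dx * math.sin(t) + dy * math.cos(t)
    canvas[y0:y1, x0:x1] += amplitude * np.exp(
        -0.5 * ((u / sigma_long) ** 2 + (v / sigma_short) ** 2)
    )


def render_texture(spec: SyntheticSpec) -> GrayImage:
    """Render the noise-free primitive field on the background canvas.

    Dots are isotropic Gaussians of scale ``dot_radius``; rods are
    anisotropic Gaussians with axial scale rod_length/2 and transverse
    scale rod_width/2.  Primitive centers are uniform in the ROI disk,
    shrunk by the primitive extent so profiles stay inside.
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    canvas = np.full((size, size), spec.background_level, dtype=np.float64)
    center = size / 2.0
    if spec.label == 1:
        sigma_long, sigma_short = spec.rod_length / 2.0, spec.rod_width / 2.0
    else:
        sigma_long = sigma_short = spec.dot_radius
    margin = 3.0 * sigma_long
    place_radius = spec.roi_radius - margin
    base_angle = rng.uniform(0.0, 180.0)
    for _ in range(spec.n_primitives):
        # uniform in the disk via sqrt radius
        r = place_radius * math.sqrt(rng.uniform())
        t = rng.uniform(0.0, 2.0 * math.pi)
        cx, cy = center + r * math.cos(t), center + r * math.sin(t)
        if spec.label == 1:
            angle = base_angle + rng.uniform(-spec.rod_angle_jitter, spec.rod_angle_jitter)
        else:
            angle = 0.0
        _add_blob(canvas, cx, cy, sigma_long, sigma_short, angle, spec.primitive_contrast)
    return GrayImage(np.clip(canvas, 0.0, 1.0))


def apply_speckle(img: GrayImage, sigma: float, seed: int) -> GrayImage:
    """Multiplicative speckle: I·(1 + σ·η), η ~ N(0, 1) i.i.d. per pixel."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return img
    rng = np.random.default_rng(seed)
    noisy = img.pixels * (1.0 + sigma * rng.standard_normal(img.pixels.shape))
    return GrayImage(np.clip(noisy, 0.0, 1.0))


def generate_dataset(
    n_per_class: int,
    out_dir: str | Path,
    master_seed: int = 0,
    spec: SyntheticSpec | None = None,
) -> Path:
    """Write a balanced labeled dataset and its annotation manifest.

    Produces ``2·n_per_class`` 16-bit PNGs named ``<image_id>.png`` plus
    ``manifest.csv`` in the manifest dialect read by
    :func:`wbovw.imaging_io.load_manifest`.  Per-image seeds are spawned
    deterministically from ``master_seed``.  Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base = spec if spec is not None else SyntheticSpec(label=0)
    ss = np.random.SeedSequence(master_seed)
    seeds = ss.generate_state(4 * n_per_class) % (2**31)
    rows = ["image_id,center_x,center_y,radius,label"]
    idx = 0
    for label, name in ((0, "normal"), (1, "fgr")):
        for i in range(n_per_class):
            img_spec = replace(base, label=label, seed=int(seeds[idx]))
            clean = render_texture(img_spec)
            noisy = apply_speckle(clean, img_spec.speckle_sigma, int(seeds[idx + 1]))
            idx += 2
            image_id = f"{name}_{i:03d}"
            arr16 = np.round(noisy.pixels * 65535.0).astype(np.uint16)
            iio.imwrite(out_dir / f"{image_id}.png", arr16)
            c = img_spec.image_size / 2.0
            rows.append(
                f"{image_id},{c:.1f},{c:.1f},{img_spec.roi_radius},{name}"
            )
    manifest = out_dir / "manifest.csv"
    manifest.write_text("\n".join(rows) + "\n")
    return manifest
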
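"""Fundus image containers, contrast enhancement, normalization and augmentation.

The preprocessing stage mirrors a standard retinal-screening pipeline:
contrast-limited adaptive histogram equalization (CLAHE) on the luminance
channel to lift lesion contrast without amplifying sensor noise, a linear
rescale of pixel values from [0, 1] to [-1, 1] for the network input, and
label-preserving geometric/photometric augmentation restricted to training
folds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image
from skimage import exposure, transform

__all__ = [
    "FundusImage",
    "AugmentationParams",
    "clahe_enhance",
    "normalize_to_signed_range",
    "augment",
    "sample_transform",
    "apply_transform",
    "save_image",
    "load_image",
]

#: BT.601 luma weights, used wherever a scalar luminance is needed.
_LUMA = np.array([0.299, 0.587, 0.114])

_GRADES = (0, 1, 2, 3, 4)


@dataclass(frozen=True)
class FundusImage:
    """A square RGB fundus photograph with an integer severity grade.

    Parameters
    ----------
    pixels
        ``(H, W, 3)`` float array, all values inside ``value_range``.
    value_range
        Declared pixel interval, either ``(0.0, 1.0)`` or ``(-1.0, 1.0)``.
    grade
        Diabetic-retinopathy severity, 0 (normal) through 4 (proliferative).
    id
        Opaque identifier used in manifests and leak checks.
    """

    pixels: np.ndarray
    value_range: tuple[float, float] = (0.0, 1.0)
    grade: int = 0
    id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"pixels must be (H, W, 3), got {px.shape}")
        h, w = px.shape[:2]
        if h != w:
            raise ValueError(f"image field must be square, got {h}x{w}")
        if h < 64:
            raise ValueError(f"image side must be >= 64 pixels, got {h}")
        lo, hi = self.value_range
        if px.min() < lo - 1e-9 or px.max() > hi + 1e-9:
            raise ValueError(
                f"pixel values [{px.min():.4g}, {px.max():.4g}] outside the "
                f"declared range [{lo}, {hi}]"
            )
        if self.grade not in _GRADES:
            raise ValueError(f"grade must be one of {_GRADES}, got {self.grade}")
        object.__setattr__(self, "pixels", px)

    @property
    def size(self) -> int:
        return self.pixels.shape[0]

    def luminance(self) -> np.ndarray:
        """Scalar luminance map in the image's own value range."""
        return self.pixels @ _LUMA


def _well_ordered(iv: tuple[float, float], name: str) -> None:
    if iv[0] > iv[1]:
        raise ValueError(f"{name} interval {iv} is not well ordered")


@dataclass(frozen=True)
class AugmentationParams:
    """Label-preserving augmentation settings.

    Geometric transforms (rotation within +/- ``max_rotation_deg``, flips,
    isotropic scaling, translation as a fraction of the side) and photometric
    jitter (brightness shift, contrast gain about the mean, saturation gain).
    Each family has an ``enabled`` switch; with everything disabled
    :func:`augment` is the identity.
    """

    max_rotation_deg: float = 15.0
    flip_horizontal: float = 0.5
    flip_vertical: float = 0.5
    scale_range: tuple[float, float] = (0.9, 1.1)
    translate_range: tuple[float, float] = (-0.05, 0.05)
    brightness_range: tuple[float, float] = (-0.1, 0.1)
    contrast_range: tuple[float, float] = (0.9, 1.1)
    saturation_range: tuple[float, float] = (0.9, 1.1)
    enable_rotation: bool = True
    enable_flips: bool = True
    enable_scale: bool = True
    enable_translation: bool = True
    enable_photometric: bool = True

    def __post_init__(self) -> None:
        if self.max_rotation_deg < 0:
            raise ValueError("max_rotation_deg must be >= 0")
        for p, name in ((self.flip_horizontal, "flip_horizontal"),
                        (self.flip_vertical, "flip_vertical")):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1]")
        for iv, name in ((self.scale_range, "scale_range"),
                         (self.translate_range, "translate_range"),
                         (self.brightness_range, "brightness_range"),
                         (self.contrast_range, "contrast_range"),
                         (self.saturation_range, "saturation_range")):
            _well_ordered(iv, name)

    @property
    def any_geometric(self) -> bool:
        return (self.enable_rotation or self.enable_flips
                or self.enable_scale or self.enable_translation)


def clahe_enhance(img: FundusImage, clip_limit: float = 2.0,
                  tile_grid: tuple[int, int] = (8, 8)) -> FundusImage:
    """Contrast-limited adaptive histogram equalization on the luminance channel.

    The RGB image is decomposed into luminance and chroma; CLAHE is applied to
    luminance only and the chroma is rescaled multiplicatively, so hue is
    approximately preserved and lesion color cues survive.  ``clip_limit``
    follows the familiar convention where ~1 disables clipping benefit and
    2-4 is typical; internally it is mapped onto the histogram-fraction
    convention of :func:`skimage.exposure.equalize_adapthist`.

    A constant-luminance image is returned unchanged: its histogram is a
    single spike and we define the equalization of a flat field as the
    identity.
    """
    if img.value_range != (0.0, 1.0):
        raise ValueError("clahe_enhance expects pixels in [0, 1]")
    if clip_limit <= 0:
        raise ValueError("clip_limit must be positive")
    ty, tx = int(tile_grid[0]), int(tile_grid[1])
    h, w = img.pixels.shape[:2]
    if ty <= 0 or ty > h:
        raise ValueError(f"tile grid rows={ty} invalid for image height {h}")
    if tx <= 0 or tx > w:
        raise ValueError(f"tile grid cols={tx} invalid for image width {w}")

    lum = img.luminance()
    if np.ptp(lum) < 1e-9:
        return replace(img, pixels=img.pixels.copy())

    kernel = (max(1, h // ty), max(1, w // tx))
    lum_eq = exposure.equalize_adapthist(
        np.clip(lum, 0.0, 1.0), kernel_size=kernel,
        clip_limit=min(1.0, clip_limit / 100.0))
    gain = lum_eq / np.maximum(lum, 1e-6)
    out = np.clip(img.pixels * gain[..., None], 0.0, 1.0)
    return replace(img, pixels=out)


def normalize_to_signed_range(img: FundusImage) -> FundusImage:
    """Map pixels linearly from [0, 1] to [-1, 1] (x -> 2x - 1)."""
    if img.value_range == (-1.0, 1.0):
        raise ValueError("image is already in [-1, 1]; refusing to normalize twice")
    if img.value_range != (0.0, 1.0):
        raise ValueError(f"expected value_range (0, 1), got {img.value_range}")
    return replace(img, pixels=2.0 * img.pixels - 1.0, value_range=(-1.0, 1.0))


def denormalize_from_signed_range(img: FundusImage) -> FundusImage:
    """Inverse of :func:`normalize_to_signed_range` (x -> (x + 1) / 2)."""
    if img.value_range != (-1.0, 1.0):
        raise ValueError(f"expected value_range (-1, 1), got {img.value_range}")
    return replace(img, pixels=(img.pixels + 1.0) / 2.0, value_range=(0.0, 1.0))


def _darkest_corner(px: np.ndarray) -> np.ndarray:
    """RGB value of the darkest of the four corner pixels.

    Rotating or translating a fundus photograph exposes border area; filling
    with the darkest corner mimics the black camera surround.
    """
    corners = np.stack([px[0, 0], px[0, -1], px[-1, 0], px[-1, -1]])
    return corners[np.argmin(corners @ _LUMA)]


def sample_transform(params: AugmentationParams,
                     rng: np.random.Generator) -> dict:
    """Draw one concrete augmentation (angle, scale, shifts, flips, jitter).

    The rotation angle is uniform in ``[-max_rotation_deg,
    +max_rotation_deg]``; translations are fractions of the image side.
    """
    tf = {"angle": 0.0, "scale": 1.0, "tx": 0.0, "ty": 0.0,
          "flip_h": False, "flip_v": False,
          "brightness": 0.0, "contrast": 1.0, "saturation": 1.0}
    if params.enable_rotation:
        tf["angle"] = rng.uniform(-params.max_rotation_deg,
                                  params.max_rotation_deg)
    if params.enable_scale:
        tf["scale"] = rng.uniform(*params.scale_range)
    if params.enable_translation:
        tf["tx"] = rng.uniform(*params.translate_range)
        tf["ty"] = rng.uniform(*params.translate_range)
    if params.enable_flips:
        tf["flip_h"] = rng.random() < params.flip_horizontal
        tf["flip_v"] = rng.random() < params.flip_vertical
    if params.enable_photometric:
        tf["brightness"] = rng.uniform(*params.brightness_range)
        tf["contrast"] = rng.uniform(*params.contrast_range)
        tf["saturation"] = rng.uniform(*params.saturation_range)
    return tf


def apply_transform(img: FundusImage, tf: dict,
                    params: AugmentationParams) -> FundusImage:
    """Apply a sampled augmentation; the grade label is never altered."""
    px = img.pixels
    lo, hi = img.value_range

    if params.any_geometric:
        h = px.shape[0]
        angle, scale = tf["angle"], tf["scale"]
        tx, tyr = tf["tx"] * h, tf["ty"] * h
        flip_h, flip_v = tf["flip_h"], tf["flip_v"]

        centre = (h - 1) / 2.0
        shift = transform.AffineTransform(translation=(-centre, -centre))
        core = transform.AffineTransform(
            rotation=np.deg2rad(angle), scale=(scale, scale))
        unshift = transform.AffineTransform(translation=(centre + tx, centre + tyr))
        tform = shift + core + unshift

        fill = _darkest_corner(px)
        chans = []
        for c in range(3):
            chans.append(transform.warp(
                px[..., c], tform.inverse, order=1,
                mode="constant", cval=float(fill[c]), preserve_range=True))
        px = np.stack(chans, axis=-1)
        if flip_h:
            px = px[:, ::-1]
        if flip_v:
            px = px[::-1, :]

    if params.enable_photometric:
        b = tf["brightness"] * (hi - lo)
        mean = px.mean()
        px = (px - mean) * tf["contrast"] + mean + b
        lum = (px @ _LUMA)[..., None]
        px = lum + (px - lum) * tf["saturation"]

    if params.any_geometric or params.enable_photometric:
        px = np.clip(px, lo, hi)
    else:
        px = px.copy()
    return replace(img, pixels=px)


def augment(img: FundusImage, params: AugmentationParams,
            rng: np.random.Generator) -> FundusImage:
    """Draw one random label-preserving augmentation of ``img``.

    Exposed borders after rotation / translation are filled with the darkest
    corner value; photometric jitter is clipped back into the declared value
    range.  Fully deterministic given ``rng``; with every transform family
    disabled the image is returned bit-identical.
    """
    return apply_transform(img, sample_transform(params, rng), params)


# ---------------------------------------------------------------------------
# File I/O: 8-bit PNG/JPEG plus a JSON sidecar recording range/grade/id.

def save_image(img: FundusImage, path: str | Path) -> Path:
    """Write an 8-bit image file plus a ``.json`` sidecar with metadata."""
    path = Path(path)
    lo, hi = img.value_range
    u8 = np.round((img.pixels - lo) / (hi - lo) * 255.0).astype(np.uint8)
    Image.fromarray(u8).save(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(
        {"value_range": list(img.value_range), "grade": int(img.grade),
         "id": img.id}))
    return path


def load_image(path: str | Path) -> FundusImage:
    """Read an image written by :func:`save_image` (sidecar restores metadata)."""
    path = Path(path)
    u8 = np.asarray(Image.open(path).convert("RGB"), dtype=np.float64)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = {"value_range": [0.0, 1.0], "grade": 0, "id": path.stem}
    if sidecar.exists():
        meta.update(json.loads(sidecar.read_text()))
    lo, hi = meta["value_range"]
    px = u8 / 255.0 * (hi - lo) + lo
    return FundusImage(pixels=px, value_range=(float(lo), float(hi)),
                       grade=int(meta["grade"]), id=str(meta["id"]))
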
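"""Synthetic graded fundus-image generator.

Emulates the visual vocabulary a retinopathy grader relies on: a dark
circular retinal field with a radial vignette, one bright optic disc,
curvilinear vessels, and grade-dependent lesions — microaneurysms (small
round dark-red dots), hemorrhages (larger irregular red blotches), exudates
(yellow-white deposits) and, at the proliferative grade, neovascular tufts
near the disc.  Lesion counts are Poisson with grade-dependent means that
increase monotonically with severity, so severity is a learnable signal.

Class composition can reproduce the heavy class imbalance of real screening
cohorts (roughly 73% normal, with the severe and proliferative grades below
3% each).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocessing import FundusImage, save_image

__all__ = [
    "LesionModel",
    "DatasetSpec",
    "EYEPACS_CLASS_COUNTS",
    "scaled_class_counts",
    "generate_image",
    "generate_image_with_stats",
    "generate_dataset",
    "write_dataset",
]

#: Per-grade image counts of the EyePACS screening cohort (grades 0..4).
EYEPACS_CLASS_COUNTS = (25783, 2459, 5304, 878, 703)


def scaled_class_counts(n_images: int,
                        base: tuple[int, ...] = EYEPACS_CLASS_COUNTS) -> tuple[int, ...]:
    """Integer class counts summing to ``n_images`` with ``base``'s proportions.

    Largest-remainder apportionment; ties broken toward the lower grade.
    """
    base_arr = np.asarray(base, dtype=float)
    quota = base_arr / base_arr.sum() * n_images
    counts = np.floor(quota).astype(int)
    remainder = quota - counts
    short = n_images - counts.sum()
    for idx in np.argsort(-remainder, kind="stable")[:short]:
        counts[idx] += 1
    return tuple(int(c) for c in counts)


@dataclass(frozen=True)
class LesionModel:
    """Expected lesion counts per image as a function of grade (0..4).

    Rates must be nonnegative, non-decreasing in grade, and exactly zero at
    grade 0 (a normal retina has no lesions).  Radii are in pixels at the
    reference size of 224 and scale linearly with image size.
    """

    microaneurysm_rate: tuple[float, ...] = (0.0, 3.0, 6.0, 9.0, 12.0)
    hemorrhage_rate: tuple[float, ...] = (0.0, 0.0, 2.0, 4.0, 6.0)
    exudate_rate: tuple[float, ...] = (0.0, 0.0, 2.0, 4.0, 6.0)
    tuft_rate: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0, 3.0)
    microaneurysm_radius: tuple[float, float] = (1.5, 3.0)
    hemorrhage_radius: tuple[float, float] = (4.0, 8.0)
    exudate_radius: tuple[float, float] = (4.5, 8.5)
    microaneurysm_color: tuple[float, ...] = (0.30, 0.04, 0.04)
    hemorrhage_color: tuple[float, ...] = (0.42, 0.06, 0.06)
    exudate_color: tuple[float, ...] = (0.96, 0.92, 0.60)
    color_sd: float = 0.02

    def __post_init__(self) -> None:
        for name in ("microaneurysm_rate", "hemorrhage_rate",
                     "exudate_rate", "tuft_rate"):
            rates = np.asarray(getattr(self, name), dtype=float)
            if rates.shape != (5,):
                raise ValueError(f"{name} must have one rate per grade (5)")
            if (rates < 0).any():
                raise ValueError(f"{name} must be nonnegative")
            if (np.diff(rates) < 0).any():
                raise ValueError(f"{name} must be non-decreasing in grade")
            if rates[0] != 0.0:
                raise ValueError(f"{name} must be exactly 0 at grade 0")


@dataclass(frozen=True)
class DatasetSpec:
    """Composition of a synthetic dataset.

    Exactly one of ``class_counts`` (exact per-grade counts) or
    ``class_probs`` (multinomial sampling) should be given; with neither,
    grades are drawn uniformly.
    """

    n_images: int = 100
    image_size: int = 224
    seed: int = 0
    class_counts: tuple[int, ...] | None = None
    class_probs: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_images < 0:
            raise ValueError("n_images must be >= 0")
        if self.class_counts is not None:
            counts = np.asarray(self.class_counts)
            if counts.shape != (5,) or (counts < 0).any():
                raise ValueError("class_counts must be 5 nonnegative integers")
            if counts.sum() != self.n_images:
                raise ValueError("class_counts must sum to n_images")
        if self.class_probs is not None:
            probs = np.asarray(self.class_probs, dtype=float)
            if probs.shape != (5,) or (probs < 0).any():
                raise ValueError("class_probs must be 5 nonnegative numbers")
            if abs(probs.sum() - 1.0) > 1e-9:
                raise ValueError("class_probs must sum to 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DatasetSpec":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("class_counts", "class_probs"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


# ---------------------------------------------------------------------------
# drawing primitives (all operate on an (H, W, 3) float canvas in place)

def _soft_disk(size: int, cy: float, cx: float, r: float,
               softness: float = 1.0) -> np.ndarray:
    """Full-frame anti-aliased disk alpha mask (used for large features)."""
    yy, xx = np.ogrid[:size, :size]
    d = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    return np.clip((r - d) / max(softness, 1e-6), 0.0, 1.0)


def _paint(canvas: np.ndarray, alpha: np.ndarray, color: np.ndarray) -> None:
    canvas *= (1.0 - alpha[..., None])
    canvas += alpha[..., None] * color


def _stamp_disk(mask: np.ndarray, cy: float, cx: float, r: float,
                softness: float) -> None:
    """Max-accumulate a soft disk into ``mask`` touching only its bounding box."""
    size = mask.shape[0]
    pad = int(np.ceil(r + softness)) + 1
    y0, y1 = max(0, int(cy) - pad), min(size, int(cy) + pad + 1)
    x0, x1 = max(0, int(cx) - pad), min(size, int(cx) + pad + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.ogrid[y0:y1, x0:x1]
    d = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    patch = np.clip((r - d) / max(softness, 1e-6), 0.0, 1.0)
    np.maximum(mask[y0:y1, x0:x1], patch, out=mask[y0:y1, x0:x1])


def _soft_disk_local(size: int, cy: float, cx: float, r: float,
                     softness: float) -> np.ndarray:
    mask = np.zeros((size, size), dtype=float)
    _stamp_disk(mask, cy, cx, r, softness)
    return mask


def _bezier_points(p0, p1, p2, n: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    return ((1 - t) ** 2) * p0 + 2 * (1 - t) * t * p1 + (t ** 2) * p2


def _draw_curve(canvas: np.ndarray, p0, p1, p2, width: float,
                color: np.ndarray, alpha: float = 0.85) -> None:
    size = canvas.shape[0]
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    # sample densely enough that consecutive stamps overlap
    arclen = np.linalg.norm(p1 - p0) + np.linalg.norm(p2 - p1)
    n = max(8, int(2 * arclen / max(width, 0.5)))
    pts = _bezier_points(p0, p1, p2, n)
    mask = np.zeros(canvas.shape[:2], dtype=float)
    for cy, cx in pts:
        if -width <= cy < size + width and -width <= cx < size + width:
            _stamp_disk(mask, cy, cx, width, softness=0.8)
    _paint(canvas, alpha * mask, color)


def _lesion_site(rng: np.random.Generator, size: int,
                 field_r: float) -> tuple[float, float]:
    """Uniform position inside the retinal field, away from the rim."""
    centre = (size - 1) / 2.0
    r = field_r * 0.85 * np.sqrt(rng.random())
    theta = rng.uniform(0.0, 2.0 * np.pi)
    return centre + r * np.sin(theta), centre + r * np.cos(theta)


def _jitter_color(rng: np.random.Generator, color, sd: float) -> np.ndarray:
    return np.clip(np.asarray(color) + rng.normal(0.0, sd, 3), 0.0, 1.0)


def generate_image(grade: int, size: int, model: LesionModel,
                   rng: np.random.Generator, id: str = "") -> FundusImage:
    """Render one synthetic fundus image of the requested severity grade.

    Deterministic given the generator state.  Grade 0 places no lesion
    primitives; lesion counts for the other grades are Poisson draws from
    the model's grade-dependent rates.
    """
    img, _ = generate_image_with_stats(grade, size, model, rng, id=id)
    return img


def generate_image_with_stats(grade: int, size: int, model: LesionModel,
                              rng: np.random.Generator, id: str = ""
                              ) -> tuple[FundusImage, dict]:
    """Like :func:`generate_image` but also returns placed-lesion statistics.

    The stats dict holds the drawn count and the total nominal area
    (sum of pi * r^2 over placed primitives) per lesion class, which lets
    tests verify the Poisson rates and the area-vs-grade monotonicity
    without image processing.
    """
    if grade not in range(5):
        raise ValueError(f"grade must be 0-4, got {grade}")
    if size < 64:
        raise ValueError(f"image size must be >= 64, got {size}")
    scale = size / 224.0
    centre = (size - 1) / 2.0
    field_r = 0.48 * size

    # retinal field with radial vignette over black surround
    yy, xx = np.ogrid[:size, :size]
    d = np.sqrt((yy - centre) ** 2 + (xx - centre) ** 2)
    vignette = np.clip(1.0 - 0.55 * (d / field_r) ** 2, 0.0, 1.0)
    in_field = _soft_disk(size, centre, centre, field_r, softness=1.5 * scale)
    base = _jitter_color(rng, (0.58, 0.27, 0.09), model.color_sd)
    canvas = np.zeros((size, size, 3), dtype=float)
    canvas += (vignette * in_field)[..., None] * base

    # optic disc: bright ellipse offset from centre
    disc_r = rng.uniform(0.062, 0.067) * size
    disc_theta = rng.uniform(0.0, 2.0 * np.pi)
    disc_cy = centre + 0.55 * field_r * np.sin(disc_theta)
    disc_cx = centre + 0.55 * field_r * np.cos(disc_theta)
    disc_alpha = _soft_disk(size, disc_cy, disc_cx, disc_r, softness=2.0 * scale)
    _paint(canvas, 0.95 * disc_alpha,
           _jitter_color(rng, (0.95, 0.86, 0.62), model.color_sd))

    # vessels: curvilinear strokes radiating from the disc
    vessel_color = np.array((0.38, 0.10, 0.05))
    n_vessels = int(rng.integers(3, 9))
    for _ in range(n_vessels):
        ang = rng.uniform(0.0, 2.0 * np.pi)
        reach = rng.uniform(0.7, 1.5) * field_r
        p0 = (disc_cy, disc_cx)
        p2 = (disc_cy + reach * np.sin(ang), disc_cx + reach * np.cos(ang))
        mid = (np.asarray(p0) + np.asarray(p2)) / 2.0
        perp = np.array([-(p2[1] - p0[1]), p2[0] - p0[0]])
        p1 = mid + rng.uniform(-0.25, 0.25) * perp
        _draw_curve(canvas, p0, p1, p2, width=rng.uniform(1.0, 2.2) * scale,
                    color=vessel_color, alpha=0.8)

    # lesions (Poisson counts; grade-0 rates are exactly zero)
    stats = {"microaneurysm_count": 0, "hemorrhage_count": 0,
             "exudate_count": 0, "tuft_count": 0,
             "microaneurysm_area": 0.0, "hemorrhage_area": 0.0,
             "exudate_area": 0.0}
    for _ in range(rng.poisson(model.microaneurysm_rate[grade])):
        cy, cx = _lesion_site(rng, size, field_r)
        r = rng.uniform(*model.microaneurysm_radius) * scale
        stats["microaneurysm_count"] += 1
        stats["microaneurysm_area"] += np.pi * r ** 2
        _paint(canvas, 0.9 * _soft_disk_local(size, cy, cx, r, softness=0.7 * scale),
               _jitter_color(rng, model.microaneurysm_color, model.color_sd))
    for _ in range(rng.poisson(model.hemorrhage_rate[grade])):
        cy, cx = _lesion_site(rng, size, field_r)
        r = rng.uniform(*model.hemorrhage_radius) * scale
        stats["hemorrhage_count"] += 1
        stats["hemorrhage_area"] += np.pi * r ** 2
        # irregular blotch: union of a few offset disks
        alpha = np.zeros(canvas.shape[:2])
        for _ in range(3):
            oy, ox = rng.normal(0.0, 0.4 * r, 2)
            _stamp_disk(alpha, cy + oy, cx + ox, rng.uniform(0.6, 1.0) * r,
                        softness=1.2 * scale)
        _paint(canvas, 0.85 * alpha,
               _jitter_color(rng, model.hemorrhage_color, model.color_sd))
    for _ in range(rng.poisson(model.exudate_rate[grade])):
        cy, cx = _lesion_site(rng, size, field_r)
        r = rng.uniform(*model.exudate_radius) * scale
        stats["exudate_count"] += 1
        stats["exudate_area"] += np.pi * r ** 2
        _paint(canvas, 0.9 * _soft_disk_local(size, cy, cx, r, softness=1.5 * scale),
               _jitter_color(rng, model.exudate_color, model.color_sd))
    for _ in range(rng.poisson(model.tuft_rate[grade])):
        # neovascular tuft: cluster of short fine curls near the disc
        stats["tuft_count"] += 1
        ty = disc_cy + rng.normal(0.0, 2.5 * disc_r)
        tx = disc_cx + rng.normal(0.0, 2.5 * disc_r)
        for _ in range(4):
            ang = rng.uniform(0.0, 2.0 * np.pi)
            reach = rng.uniform(0.02, 0.05) * size
            p2 = (ty + reach * np.sin(ang), tx + reach * np.cos(ang))
            p1 = (ty + rng.normal(0.0, reach), tx + rng.normal(0.0, reach))
            _draw_curve(canvas, (ty, tx), p1, p2, width=0.8 * scale,
                        color=np.array((0.5, 0.12, 0.08)), alpha=0.9)

    # sensor noise, clipped into range
    canvas += rng.normal(0.0, 0.01, canvas.shape)
    canvas = np.clip(canvas, 0.0, 1.0)
    canvas *= in_field[..., None]  # keep the surround black
    img = FundusImage(pixels=canvas, value_range=(0.0, 1.0), grade=grade,
                      id=id or f"g{grade}")
    return img, stats


def _draw_grades(spec: DatasetSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.class_counts is not None:
        counts = np.asarray(spec.class_counts)
    elif spec.class_probs is not None:
        counts = rng.multinomial(spec.n_images, spec.class_probs)
        for g in np.flatnonzero((np.asarray(spec.class_probs) > 0) & (counts == 0)):
            warnings.warn(f"grade {g} has positive probability but drew 0 images")
    else:
        counts = rng.multinomial(spec.n_images, [0.2] * 5)
    return np.repeat(np.arange(5), counts)


def generate_dataset(spec: DatasetSpec,
                     model: LesionModel | None = None
                     ) -> tuple[list[FundusImage], pd.DataFrame]:
    """Generate a full dataset and its manifest.

    Returns the images plus a manifest DataFrame with columns
    ``id, grade, seed``.  Each image gets its own child seed derived from
    ``spec.seed``, so two runs with the same spec are identical and any
    single image can be regenerated from its manifest row.
    """
    model = model or LesionModel()
    root = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(root.spawn(1)[0])
    grades = _draw_grades(spec, rng)

    images: list[FundusImage] = []
    rows = []
    children = root.spawn(len(grades) + 1)[1:]
    for i, (grade, child) in enumerate(zip(grades, children)):
        child_seed = int(child.generate_state(1, np.uint32)[0])
        img_id = f"img{i:05d}_g{grade}"
        img = generate_image(int(grade), spec.image_size, model,
                             np.random.default_rng(child_seed), id=img_id)
        images.append(img)
        rows.append({"id": img_id, "grade": int(grade), "seed": child_seed})
    manifest = pd.DataFrame(rows, columns=["id", "grade", "seed"])
    return images, manifest


def write_dataset(spec: DatasetSpec, out_dir: str | Path,
                  model: LesionModel | None = None) -> pd.DataFrame:
    """Generate a dataset and write PNGs plus a CSV manifest to ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    images, manifest = generate_dataset(spec, model)
    for img in images:
        save_image(img, out_dir / f"{img.id}.png")
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
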
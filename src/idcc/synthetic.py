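"""Seeded synthetic fluorescence-microscopy images with exact ground truth.

Each named profile emulates one benchmark-dataset regime:

* ``idcia_like``  — 800x600 frames, 83 +/- 104 cells, bright Gaussian-shaded
  cells on a dark, unevenly illuminated background (neural-progenitor
  immunocytochemistry);
* ``vgg_like``    — 256x256 frames, 174 +/- 64 cells, small blurred bright
  blobs on a dark field (simulated bacterial fluorescence);
* ``adc_like``    — 400x400 frames, 165 +/- 44 cells, bright background with
  darker cell boundaries (adipocyte histology regions of interest).

Per-image cell counts are drawn from a lognormal distribution whose first
two moments are matched to the profile's (mean, sd).  A lognormal is used
rather than a truncated normal because one regime's sd exceeds its mean
(104 vs 83), which makes moment preservation under truncation at zero
impossible; the lognormal's support is already positive, so flooring the
rounded draw at 1 cell leaves the mean essentially unchanged at these
parameter scales.

Cell centers are placed by rejection sampling with a minimum pairwise
separation; each cell is rendered as a Gaussian-shaded disk (dark modes) or
a darker-rimmed region (bright-field mode).  The rendered label map and the
exact disk centers are recorded as ground truth.  All randomness flows from
``(seed, image_index)`` so datasets are bit-reproducible, including under
parallel generation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io_formats import CentroidSet, write_annotations, write_image

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SynthProfile:
    """Parameter bundle for one synthetic-dataset regime."""

    name: str = "custom"
    width: int = 256
    height: int = 256
    count_mean: float = 20.0
    count_sd: float = 0.0
    radius_range: tuple[float, float] = (3.0, 8.0)
    cell_peak_intensity: tuple[int, int] = (180, 255)
    background_mode: str = "dark_gradient"  # or "bright_field"
    illumination_amplitude: float = 40.0
    noise_sd: float = 0.0
    min_separation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.count_mean <= 0:
            raise ValidationError("count_mean must be > 0")
        if self.count_sd < 0:
            raise ValidationError("count_sd must be >= 0")
        lo, hi = self.radius_range
        if not (0 < lo <= hi < min(self.width, self.height) / 4):
            raise ValidationError(
                "radius_range must lie within (0, min(W, H)/4)"
            )
        if self.background_mode not in ("dark_gradient", "bright_field"):
            raise ValidationError(f"unknown background_mode {self.background_mode!r}")


@dataclass
class SynthSample:
    """One generated image with its exact ground truth."""

    image: np.ndarray  # GrayImage
    truth: CentroidSet
    label_map: np.ndarray  # 0 = background, k = cell k


def named_profile(name: str, seed: int = 0) -> SynthProfile:
    """Instantiate one of the named dataset profiles."""
    if name == "idcia_like":
        return SynthProfile(
            name=name, width=800, height=600, count_mean=83, count_sd=104,
            radius_range=(3, 6), cell_peak_intensity=(180, 255),
            background_mode="dark_gradient", illumination_amplitude=40,
            noise_sd=8, min_separation=10, seed=seed,
        )
    if name == "vgg_like":
        return SynthProfile(
            name=name, width=256, height=256, count_mean=174, count_sd=64,
            radius_range=(2, 4), cell_peak_intensity=(180, 255),
            background_mode="dark_gradient", illumination_amplitude=40,
            noise_sd=8, min_separation=6, seed=seed,
        )
    if name == "adc_like":
        return SynthProfile(
            name=name, width=400, height=400, count_mean=165, count_sd=44,
            radius_range=(5, 9), cell_peak_intensity=(180, 255),
            background_mode="bright_field", illumination_amplitude=20,
            noise_sd=6, min_separation=12, seed=seed,
        )
    raise ValidationError(f"unknown profile {name!r}")


PROFILE_NAMES = ("idcia_like", "vgg_like", "adc_like")


def _image_rng(profile: SynthProfile, index: int) -> np.random.Generator:
    """Independent per-image stream derived from (seed, index)."""
    return np.random.default_rng(np.random.SeedSequence([profile.seed, index]))


def draw_count(profile: SynthProfile, rng: np.random.Generator) -> int:
    """Sample a per-image cell count: moment-matched lognormal, floored at 1.

    With sd = 0 the distribution degenerates to round(count_mean).
    """
    if profile.count_sd == 0:
        return max(1, round(profile.count_mean))
    cv2 = (profile.count_sd / profile.count_mean) ** 2
    sigma2 = np.log1p(cv2)
    mu = np.log(profile.count_mean) - sigma2 / 2.0
    draw = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2))
    return max(1, round(draw))


def _place_centers(
    n: int, profile: SynthProfile, rng: np.random.Generator
) -> list[tuple[float, float]]:
    """Rejection-sample up to n (cx, cy) centers honoring min_separation.

    Gives up after 10*n attempts and returns however many were placed,
    with a logged warning; callers record the actual number as truth.
    """
    centers: list[tuple[float, float]] = []
    min_sep2 = profile.min_separation**2
    budget = 10 * n
    while len(centers) < n and budget > 0:
        budget -= 1
        cx = rng.uniform(0, profile.width)
        cy = rng.uniform(0, profile.height)
        if min_sep2 > 0 and any(
            (cx - px) ** 2 + (cy - py) ** 2 < min_sep2 for px, py in centers
        ):
            continue
        centers.append((cx, cy))
    if len(centers) < n:
        logger.warning(
            "placed only %d of %d cells at separation %.1f in %dx%d",
            len(centers), n, profile.min_separation, profile.width, profile.height,
        )
    return centers


def _background(profile: SynthProfile, rng: np.random.Generator) -> np.ndarray:
    """Low-frequency illumination field as float64."""
    h, w = profile.height, profile.width
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    # One smooth sinusoidal wave with a random orientation and phase.
    fx = rng.uniform(0.5, 1.5)
    fy = rng.uniform(0.5, 1.5)
    phase = rng.uniform(0, 2 * np.pi)
    wave = 0.5 * (1 + np.cos(2 * np.pi * (fx * xx / w + fy * yy / h) + phase))
    if profile.background_mode == "dark_gradient":
        return 20.0 + profile.illumination_amplitude * wave
    return 235.0 - profile.illumination_amplitude * wave


def _render_cell(
    canvas: np.ndarray,
    label_map: np.ndarray,
    k: int,
    cx: float,
    cy: float,
    radius: float,
    peak: float,
    mode: str,
) -> None:
    """Draw cell k in place onto the canvas and label map."""
    h, w = canvas.shape
    r_int = int(np.ceil(radius))
    y0, y1 = max(0, int(cy) - r_int - 1), min(h, int(cy) + r_int + 2)
    x0, x1 = max(0, int(cx) - r_int - 1), min(w, int(cx) + r_int + 2)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1].astype(np.float64)
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    inside = d2 <= radius**2
    if mode == "dark_gradient":
        # Gaussian-shaded bright disk with an intensity floor at half peak,
        # so even the rim stays well above a dark background.
        sigma = radius / 2.0
        shade = peak * (0.5 + 0.5 * np.exp(-d2 / (2 * sigma**2)))
        region = canvas[y0:y1, x0:x1]
        region[inside] = np.maximum(region[inside], shade[inside])
    else:
        # Bright-field: slightly darker interior with a distinctly darker rim.
        rim = inside & (d2 >= (radius - 1.5) ** 2)
        interior = inside & ~rim
        region = canvas[y0:y1, x0:x1]
        region[interior] = np.minimum(region[interior], 210.0)
        region[rim] = np.minimum(region[rim], 100.0)
    label_map[y0:y1, x0:x1][inside] = k


def generate_image(profile: SynthProfile, index: int = 0) -> SynthSample:
    """Render one synthetic image; deterministic in (profile.seed, index)."""
    rng = _image_rng(profile, index)
    n = draw_count(profile, rng)
    centers = _place_centers(n, profile, rng)
    canvas = _background(profile, rng)
    label_map = np.zeros((profile.height, profile.width), dtype=np.int32)
    lo, hi = profile.radius_range
    for k, (cx, cy) in enumerate(centers, start=1):
        radius = rng.uniform(lo, hi)
        peak = rng.uniform(*profile.cell_peak_intensity)
        _render_cell(
            canvas, label_map, k, cx, cy, radius, peak, profile.background_mode
        )
    if profile.noise_sd > 0:
        canvas = canvas + rng.normal(0, profile.noise_sd, canvas.shape)
    image = np.clip(np.floor(canvas + 0.5), 0, 255).astype(np.uint8)
    truth = CentroidSet(points=list(centers), image_id=f"{profile.name}_{index:04d}")
    return SynthSample(image=image, truth=truth, label_map=label_map)


def generate_dataset(
    profile: SynthProfile, n_images: int, out_dir: str | Path
) -> pd.DataFrame:
    """Write PNGs, truth CSVs, and a manifest; returns the manifest frame.

    Layout: ``<id>.png`` and ``<id>.csv`` per image plus ``manifest.csv``
    with columns image_id, true_count, profile, seed.
    """
    if n_images < 1:
        raise ValidationError("n_images must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(n_images):
        sample = generate_image(profile, i)
        image_id = sample.truth.image_id
        write_image(sample.image, out_dir / f"{image_id}.png")
        write_annotations(sample.truth, out_dir / f"{image_id}.csv")
        rows.append(
            {
                "image_id": image_id,
                "true_count": len(sample.truth),
                "profile": profile.name,
                "seed": profile.seed,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def with_seed(profile: SynthProfile, seed: int) -> SynthProfile:
    """Copy of a profile with a different seed."""
    return replace(profile, seed=seed)
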
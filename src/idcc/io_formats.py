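"""Reading and writing images, centroid annotations, count tables, and overlays.

Conventions
-----------
Images are 2-D uint8 arrays indexed ``[row, col]`` ("GrayImage").  Centroid
coordinates are 0-based with ``x`` the column index and ``y`` the row index;
annotation CSVs carry a literal ``x,y`` header and one centroid per row.
Count tables are CSVs with an ``image_id,count`` header.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

from .exceptions import FormatError, ParseError, ValidationError

# ITU-R BT.601 luminance weights for RGB -> gray conversion.
_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass
class CentroidSet:
    """Point annotations (cell centers) for one image.

    ``points`` is a list of ``(cx, cy)`` pairs where ``cx`` is the column
    coordinate and ``cy`` the row coordinate, both 0-based floats.
    """

    points: list[tuple[float, float]] = field(default_factory=list)
    image_id: str = ""

    def __len__(self) -> int:
        return len(self.points)

    def validate_bounds(self, height: int, width: int) -> None:
        """Raise ValidationError if any point falls outside an HxW image."""
        for cx, cy in self.points:
            if not (0 <= cx < width and 0 <= cy < height):
                raise ValidationError(
                    f"centroid ({cx}, {cy}) outside image bounds "
                    f"{height}x{width} for image {self.image_id!r}"
                )


def validate_gray_image(pixels: np.ndarray) -> np.ndarray:
    """Check the GrayImage invariants and return a uint8 view/copy."""
    arr = np.asarray(pixels)
    if arr.ndim != 2 or arr.size == 0:
        raise ValidationError(f"expected a non-empty 2-D image, got shape {arr.shape}")
    if arr.min() < 0 or arr.max() > 255:
        raise ValidationError("pixel values must lie in [0, 255]")
    return arr.astype(np.uint8)


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF image as a GrayImage (2-D uint8).

    3-channel input is converted to luminance with ITU-R BT.601 weights;
    16-bit input is linearly rescaled so full scale maps to 255.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # imageio raises various types per plugin
        raise FormatError(f"cannot read image {path}: {exc}") from exc
    if arr.size == 0:
        raise ValidationError(f"zero-sized image: {path}")
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        if arr.shape[2] != 3:
            raise FormatError(
                f"unsupported channel count {arr.shape[2]} in {path}"
            )
        arr = arr.astype(np.float64) @ _LUMA_WEIGHTS
    elif arr.ndim != 2:
        raise FormatError(f"unsupported image dimensionality {arr.ndim} in {path}")
    arr = arr.astype(np.float64)
    if arr.max() > 255:  # 16-bit input
        arr = arr * (255.0 / 65535.0)
    return np.clip(np.floor(arr + 0.5), 0, 255).astype(np.uint8)


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write a GrayImage as an 8-bit grayscale PNG/TIFF."""
    iio.imwrite(Path(path), validate_gray_image(image))


def read_annotations(path: str | Path, image_id: str | None = None) -> CentroidSet:
    """Read a centroid CSV with header ``x,y`` into a CentroidSet.

    Raises ParseError naming the offending 1-based line for a missing
    header or a non-numeric row.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        lines = [ln.strip() for ln in fh if ln.strip() != ""]
    if not lines or [c.strip().lower() for c in lines[0].split(",")[:2]] != ["x", "y"]:
        raise ParseError(f"{path}: line 1: expected header 'x,y'")
    points: list[tuple[float, float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split(",")
        try:
            cx, cy = float(parts[0]), float(parts[1])
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{path}: line {lineno}: non-numeric row {line!r}") from exc
        points.append((cx, cy))
    if image_id is None:
        image_id = path.stem
    return CentroidSet(points=points, image_id=image_id)


def write_annotations(centers: CentroidSet, path: str | Path) -> None:
    """Write a CentroidSet to CSV in the ``x,y`` dialect."""
    df = pd.DataFrame(centers.points, columns=["x", "y"])
    df.to_csv(path, index=False)


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a counts CSV (``image_id,count``) into a DataFrame."""
    df = pd.read_csv(path, dtype={"image_id": str})
    missing = {"image_id", "count"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_counts(rows: Sequence[tuple[str, int]], path: str | Path) -> None:
    """Write per-image counts as a CSV with header ``image_id,count``."""
    pd.DataFrame(rows, columns=["image_id", "count"]).to_csv(path, index=False)


def _marker_palette(n: int) -> list[tuple[int, int, int]]:
    """n visually distinct RGB colors, evenly spaced in hue."""
    colors = []
    for i in range(max(n, 1)):
        r, g, b = colorsys.hsv_to_rgb(i / max(n, 1), 1.0, 1.0)
        colors.append((int(r * 255), int(g * 255), int(b * 255)))
    return colors


def write_overlay(image: np.ndarray, centers: CentroidSet, path: str | Path) -> None:
    """Render centroid markers and a corner count badge onto an RGB PNG.

    Each centroid gets a distinctly colored square marker; the total count
    is drawn in a green badge in the top-right corner.  Marker positions
    and the count value are contractual; styling is cosmetic.
    """
    image = validate_gray_image(image)
    h, w = image.shape
    centers.validate_bounds(h, w)
    rgb = np.stack([image] * 3, axis=-1)
    img = Image.fromarray(rgb, mode="RGB")
    draw = ImageDraw.Draw(img)
    palette = _marker_palette(len(centers.points))
    for (cx, cy), color in zip(centers.points, palette):
        x, y = int(round(cx)), int(round(cy))
        draw.rectangle([x - 1, y - 1, x + 1, y + 1], fill=color)
    badge_text = str(len(centers.points))
    tw = max(8 * len(badge_text), 8)
    draw.rectangle([w - tw - 10, 0, w - 1, 14], fill=(0, 160, 0))
    draw.text((w - tw - 6, 2), badge_text, fill=(255, 255, 255))
    img.save(Path(path), format="PNG")
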
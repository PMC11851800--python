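"""Contrast-limited adaptive histogram equalization (CLAHE).

The image is divided into non-overlapping square tiles (default 8x8 pixels).
Each tile's intensity histogram is clipped at a limit derived from the
``clip_limit`` parameter, the clipped excess is redistributed uniformly, and
a per-tile intensity look-up table is built from the cumulative probability
distribution of the clipped histogram:

    P(f) = sum_{i<=f} H(i) / sum_i H(i)
    p    = (p_max - p_min) * P(f) + g_min

Output pixels are bilinear blends of the LUTs of the four tiles whose
centers surround them; pixels outside the outermost tile centers clamp to
the nearest tile row/column (the classical corner/edge rule).

Numerical conventions, chosen here because no single published convention
exists:

* the absolute clip count is ``beta = max(1, clip_limit * n_tile / n_levels)``
  (the normalized-clip convention common to CLAHE implementations);
* excess is redistributed in a single uniform real-valued pass (E / L added
  to every bin) with no re-clipping, which preserves the histogram sum
  exactly — the only property the cumulative normalization requires;
* images whose sides are not multiples of the tile size are reflect-padded
  on the bottom/right and cropped after remapping;
* interpolated values are rounded half-up and clamped to [g_min, p_max].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .exceptions import ValidationError
from .io_formats import validate_gray_image


@dataclass(frozen=True)
class ClaheParams:
    """CLAHE configuration.

    tile_size : side of a square tile in pixels (8 gives 64-pixel
        neighborhoods).
    clip_limit : dimensionless clip factor c in (0, 1]; the per-bin cap is
        ``max(1, c * n_tile / n_levels)``.  0.8 gives the best illumination
        correction on immunocytochemistry images.
    n_levels : number of intensity levels L (256 for 8-bit input).
    p_min, p_max : output intensity range endpoints.
    g_min : minimum grayscale value of the normalized range (offset added
        after scaling the cumulative distribution).
    """

    tile_size: int = 8
    clip_limit: float = 0.8
    n_levels: int = 256
    p_min: int = 0
    p_max: int = 255
    g_min: int = 0

    def __post_init__(self) -> None:
        if self.tile_size < 2:
            raise ValidationError("tile_size must be >= 2")
        if not (0 < self.clip_limit <= 1):
            raise ValidationError("clip_limit must be in (0, 1]")
        if self.n_levels < 2:
            raise ValidationError("n_levels must be >= 2")
        if self.p_min >= self.p_max:
            raise ValidationError("p_min must be < p_max")
        if self.g_min > self.p_min:
            raise ValidationError("g_min must be <= p_min")


@dataclass
class Histogram:
    """Per-tile intensity histogram; counts become fractional after clipping."""

    counts: np.ndarray  # length n_levels, non-negative reals
    n_tile: int  # pixels in the tile


@dataclass
class TileMapping:
    """Intensity look-up table for one tile: input level f -> output value p."""

    lut: np.ndarray  # length n_levels, real-valued, monotone non-decreasing
    tile_row: int = 0
    tile_col: int = 0
    tile_center: tuple[float, float] = (0.0, 0.0)  # (row, col) in image coords


@dataclass
class TileGrid:
    """Result of partitioning: padded image, tile array, padding amounts."""

    padded: np.ndarray  # reflect-padded image, shape (n_rows*t, n_cols*t)
    n_rows: int
    n_cols: int
    pad_bottom: int
    pad_right: int
    tile_size: int

    def tile(self, r: int, c: int) -> np.ndarray:
        t = self.tile_size
        return self.padded[r * t : (r + 1) * t, c * t : (c + 1) * t]

    def tiles(self) -> Iterator[tuple[int, int, np.ndarray]]:
        for r in range(self.n_rows):
            for c in range(self.n_cols):
                yield r, c, self.tile(r, c)


def tile_partition(image: np.ndarray, params: ClaheParams) -> TileGrid:
    """Reflect-pad bottom/right to tile-size multiples and expose the grid."""
    image = validate_gray_image(image)
    h, w = image.shape
    t = params.tile_size
    n_rows = -(-h // t)
    n_cols = -(-w // t)
    pad_bottom = n_rows * t - h
    pad_right = n_cols * t - w
    padded = np.pad(image, ((0, pad_bottom), (0, pad_right)), mode="reflect")
    return TileGrid(padded, n_rows, n_cols, pad_bottom, pad_right, t)


def quantize_levels(image: np.ndarray, params: ClaheParams) -> np.ndarray:
    """Map 8-bit pixel values to histogram levels [0, L-1]."""
    if params.n_levels == 256:
        return image.astype(np.intp)
    return (image.astype(np.intp) * params.n_levels) // 256


def tile_histogram(tile: np.ndarray, params: ClaheParams) -> Histogram:
    """Intensity histogram of one tile: H(i) = pixels at level i."""
    levels = quantize_levels(np.asarray(tile), params)
    counts = np.bincount(levels.ravel(), minlength=params.n_levels).astype(np.float64)
    return Histogram(counts=counts, n_tile=int(tile.size))


def clip_histogram(hist: Histogram, params: ClaheParams) -> Histogram:
    """Cap every bin at beta = max(1, c*n_tile/L) and redistribute the excess.

    Redistribution is uniform and single-pass: the total excess E is added
    back as E/L to every bin (fractional counts allowed), so the histogram
    sum is preserved exactly.
    """
    beta = max(1.0, params.clip_limit * hist.n_tile / params.n_levels)
    clipped = np.minimum(hist.counts, beta)
    excess = float(hist.counts.sum() - clipped.sum())
    clipped = clipped + excess / params.n_levels
    return Histogram(counts=clipped, n_tile=hist.n_tile)


def cumulative_mapping(hist: Histogram, params: ClaheParams) -> TileMapping:
    """Build the tile LUT from the cumulative probability distribution.

    P(f) = cumulative frequency up to level f over the total frequency;
    lut[f] = (p_max - p_min) * P(f) + g_min.  The LUT is monotone
    non-decreasing and reaches p_max at the top level when g_min = p_min = 0.
    """
    total = hist.counts.sum()
    if total <= 0:
        raise ValidationError("cannot build a mapping from an all-zero histogram")
    cpd = np.cumsum(hist.counts) / total
    lut = (params.p_max - params.p_min) * cpd + params.g_min
    return TileMapping(lut=lut)


def _tile_luts(grid: TileGrid, params: ClaheParams) -> np.ndarray:
    """LUTs for every tile, shape (n_rows, n_cols, n_levels)."""
    luts = np.empty((grid.n_rows, grid.n_cols, params.n_levels))
    for r, c, tile in grid.tiles():
        hist = clip_histogram(tile_histogram(tile, params), params)
        luts[r, c] = cumulative_mapping(hist, params).lut
    return luts


def apply_clahe(image: np.ndarray, params: ClaheParams | None = None) -> np.ndarray:
    """Equalize an image: per-tile clipped LUTs blended bilinearly per pixel.

    Returns a uint8 image of the same shape, with values in
    [g_min, p_max].
    """
    if params is None:
        params = ClaheParams()
    grid = tile_partition(image, params)
    luts = _tile_luts(grid, params)
    t = grid.tile_size
    hp, wp = grid.padded.shape
    levels = quantize_levels(grid.padded, params)

    # Fractional tile-grid coordinates of each pixel relative to tile centers.
    half = (t - 1) / 2.0
    gr = (np.arange(hp) - half) / t
    gc = (np.arange(wp) - half) / t
    gr = np.clip(gr, 0.0, grid.n_rows - 1.0)
    gc = np.clip(gc, 0.0, grid.n_cols - 1.0)
    r0 = np.floor(gr).astype(np.intp)
    c0 = np.floor(gc).astype(np.intp)
    r0 = np.minimum(r0, grid.n_rows - 1)
    c0 = np.minimum(c0, grid.n_cols - 1)
    r1 = np.minimum(r0 + 1, grid.n_rows - 1)
    c1 = np.minimum(c0 + 1, grid.n_cols - 1)
    wr = (gr - r0)[:, None]
    wc = (gc - c0)[None, :]

    r0g = r0[:, None]
    r1g = r1[:, None]
    c0g = c0[None, :]
    c1g = c1[None, :]
    v00 = luts[r0g, c0g, levels]
    v01 = luts[r0g, c1g, levels]
    v10 = luts[r1g, c0g, levels]
    v11 = luts[r1g, c1g, levels]
    blended = (
        (1 - wr) * (1 - wc) * v00
        + (1 - wr) * wc * v01
        + wr * (1 - wc) * v10
        + wr * wc * v11
    )
    out = np.clip(np.floor(blended + 0.5), params.g_min, params.p_max)
    h, w = np.asarray(image).shape
    return out[:h, :w].astype(np.uint8)
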
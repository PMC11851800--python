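"""Independent brute-force reference implementations used as test oracles.

These deliberately avoid the package's vectorized code paths: histograms
are accumulated pixel by pixel, cumulative sums are explicit loops, and
the bilinear blend is evaluated with scalar arithmetic per pixel.
"""

from __future__ import annotations

import math

import numpy as np


def clahe_oracle(image: np.ndarray, tile_size: int = 8, clip_limit: float = 0.8,
                 n_levels: int = 256, p_min: int = 0, p_max: int = 255,
                 g_min: int = 0) -> np.ndarray:
    """Naive per-pixel CLAHE: recompute tile LUTs with plain loops and blend."""
    img = np.asarray(image, dtype=int)
    h, w = img.shape
    t = tile_size
    n_rows = math.ceil(h / t)
    n_cols = math.ceil(w / t)
    padded = np.pad(img, ((0, n_rows * t - h), (0, n_cols * t - w)), mode="reflect")

    def level(v: int) -> int:
        return v if n_levels == 256 else (v * n_levels) // 256

    def tile_lut(tr: int, tc: int) -> list[float]:
        hist = [0.0] * n_levels
        for i in range(tr * t, (tr + 1) * t):
            for j in range(tc * t, (tc + 1) * t):
                hist[level(int(padded[i, j]))] += 1
        beta = max(1.0, clip_limit * t * t / n_levels)
        excess = 0.0
        for f in range(n_levels):
            if hist[f] > beta:
                excess += hist[f] - beta
                hist[f] = beta
        for f in range(n_levels):
            hist[f] += excess / n_levels
        total = sum(hist)
        lut = []
        running = 0.0
        for f in range(n_levels):
            running += hist[f]
            lut.append((p_max - p_min) * (running / total) + g_min)
        return lut

    luts = [[tile_lut(r, c) for c in range(n_cols)] for r in range(n_rows)]
    out = np.empty((h, w), dtype=np.uint8)
    half = (t - 1) / 2.0
    for i in range(h):
        for j in range(w):
            gr = min(max((i - half) / t, 0.0), n_rows - 1.0)
            gc = min(max((j - half) / t, 0.0), n_cols - 1.0)
            r0 = min(int(math.floor(gr)), n_rows - 1)
            c0 = min(int(math.floor(gc)), n_cols - 1)
            r1 = min(r0 + 1, n_rows - 1)
            c1 = min(c0 + 1, n_cols - 1)
            wr = gr - r0
            wc = gc - c0
            f = level(int(padded[i, j]))
            val = ((1 - wr) * (1 - wc) * luts[r0][c0][f]
                   + (1 - wr) * wc * luts[r0][c1][f]
                   + wr * (1 - wc) * luts[r1][c0][f]
                   + wr * wc * luts[r1][c1][f])
            out[i, j] = int(min(max(math.floor(val + 0.5), g_min), p_max))
    return out
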
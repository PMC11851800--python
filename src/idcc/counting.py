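"""Centroid-based cell counting from instance masks.

For each non-background mask the bounding box of its nonzero pixels is
computed as

    x = min(cols), y = min(rows), w = max(cols) - x, h = max(rows) - y

and the cell center is the box midpoint (x + w/2, y + h/2).  The cell count
N is the number of centers.  Width and height are max - min (not
max - min + 1): centers therefore sit on the pixel-index midpoint, which
shifts them by half a pixel relative to the pixel-area centroid but has no
effect on counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .exceptions import ValidationError
from .io_formats import CentroidSet
from .segmentation import MaskSet

logger = logging.getLogger(__name__)


class BBox(NamedTuple):
    """Bounding box: top-left corner (x, y) and extents (w, h) = max - min."""

    x: int
    y: int
    w: int
    h: int


@dataclass
class CountResult:
    """Count, centers, and per-mask boxes for one image."""

    n: int
    centers: CentroidSet = field(default_factory=CentroidSet)
    bboxes: list[BBox] = field(default_factory=list)


def mask_bbox(mask: np.ndarray) -> BBox:
    """Bounding box of the nonzero pixels of a binary mask.

    ``x`` is the minimum column, ``y`` the minimum row; ``w``/``h`` are
    max - min (zero for a single-pixel extent).
    """
    rows, cols = np.nonzero(np.asarray(mask))
    if rows.size == 0:
        raise ValidationError("mask has no nonzero pixels")
    x, y = int(cols.min()), int(rows.min())
    return BBox(x=x, y=y, w=int(cols.max()) - x, h=int(rows.max()) - y)


def mask_center(bbox: BBox) -> tuple[float, float]:
    """Center point of a bounding box: (x + w/2, y + h/2), unrounded."""
    return (bbox.x + bbox.w / 2.0, bbox.y + bbox.h / 2.0)


def count_cells(
    maskset: MaskSet, skip_background: bool = True, image_id: str = ""
) -> CountResult:
    """Count cells by extracting one center per non-background mask.

    With ``skip_background`` (the default) mask 0 — the largest-area mask,
    treated as background — is excluded.  Empty masks are skipped with a
    logged warning rather than raising, for robustness to degenerate
    backend output.
    """
    if len(maskset) == 0:
        raise ValidationError("cannot count from an empty MaskSet")
    start = 1 if skip_background else 0
    centers = CentroidSet(image_id=image_id)
    bboxes: list[BBox] = []
    for idx, mask in enumerate(maskset.masks[start:], start=start):
        if not np.any(mask):
            logger.warning("skipping empty mask %d for image %r", idx, image_id)
            continue
        bbox = mask_bbox(mask)
        bboxes.append(bbox)
        centers.points.append(mask_center(bbox))
    return CountResult(n=len(centers.points), centers=centers, bboxes=bboxes)
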
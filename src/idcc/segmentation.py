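"""Prompt-free instance-mask extraction behind a pluggable backend contract.

A backend takes a grayscale image and returns a MaskSet: binary instance
masks of image shape, sorted by area descending, with index 0 treated as
the background mask.  The contract deliberately accepts no prompts (points,
boxes, or text) — mask proposal is fully automatic.

Two backends ship here:

* ``reference`` — a self-contained classical segmenter (Otsu threshold with
  auto polarity + 8-connected components) used for offline testing and as a
  dependency-free baseline;
* ``sam`` — an optional adapter around the pre-trained Segment Anything
  automatic mask generator; requires the ``segment-anything`` and ``torch``
  extras plus a model checkpoint, and raises CapabilityError when absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as label_components

from .exceptions import CapabilityError, ValidationError
from .io_formats import validate_gray_image


@dataclass
class MaskSet:
    """Ordered binary instance masks; index 0 is the background candidate."""

    masks: list[np.ndarray] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.masks)

    def __iter__(self):
        return iter(self.masks)

    def sort_by_area(self) -> "MaskSet":
        """Order masks area-descending (stable), background first."""
        self.masks.sort(key=lambda m: -int(m.sum()))
        return self

    def to_label_map(self) -> np.ndarray:
        """Stacked 16-bit label map for inspection (later masks overwrite)."""
        if not self.masks:
            raise ValidationError("empty MaskSet has no label map")
        out = np.zeros(self.masks[0].shape, dtype=np.uint16)
        for k, m in enumerate(self.masks):
            out[m.astype(bool)] = k
        return out


def reference_backend(image: np.ndarray, min_area: int = 1) -> MaskSet:
    """Classical segmenter: Otsu threshold, 8-connected components.

    Threshold polarity is chosen automatically so the foreground is the
    minority class (cells occupy less area than background in both
    dark-field fluorescence and bright-field images).  Components smaller
    than ``min_area`` pixels are discarded.  The complement of the kept
    components is the background mask.
    """
    image = validate_gray_image(image)
    if image.min() == image.max():
        # Featureless image: the whole frame is background.
        return MaskSet(
            masks=[np.ones_like(image, dtype=bool)], provenance="reference"
        )
    thr = threshold_otsu(image)
    above = image > thr
    fg = above if above.sum() <= above.size - above.sum() else ~above
    labels = label_components(fg, connectivity=2)
    masks: list[np.ndarray] = []
    union = np.zeros_like(fg)
    for k in range(1, labels.max() + 1):
        m = labels == k
        if int(m.sum()) >= min_area:
            masks.append(m)
            union |= m
    background = ~union
    out = MaskSet(masks=masks, provenance="reference")
    if background.any():
        out.masks.append(background)
    return out.sort_by_area()


def dedup_by_iou(maskset: MaskSet, iou_threshold: float) -> MaskSet:
    """Greedy IoU deduplication, largest mask wins.  Off by default everywhere;
    provided for experimenting with backends that emit near-duplicate masks."""
    kept: list[np.ndarray] = []
    for m in sorted(maskset.masks, key=lambda m: -int(m.sum())):
        dup = False
        for k in kept:
            inter = int((m & k).sum())
            union = int((m | k).sum())
            if union and inter / union > iou_threshold:
                dup = True
                break
        if not dup:
            kept.append(m)
    return MaskSet(masks=kept, provenance=maskset.provenance).sort_by_area()


def sam_backend(
    image: np.ndarray,
    checkpoint: str | None = None,
    model_type: str = "vit_h",
    generator=None,
    dedup_iou: float | None = None,
    **amg_params,
) -> MaskSet:
    """Adapter around the Segment Anything automatic mask generator.

    Runs the pre-trained generator with no prompts and converts its
    per-instance binary masks into a MaskSet.  If the generator did not
    emit a mask covering the remaining area, the complement of the union
    of instances is appended as the background mask.  Overlapping masks
    are retained as-is (no deduplication).

    ``generator`` may be any object with a ``generate(rgb_image)`` method
    returning dicts with a boolean ``"segmentation"`` entry (the upstream
    API); supplying one bypasses model loading, which is how the adapter
    contract is tested without weights.
    """
    image = validate_gray_image(image)
    if generator is None:
        generator = _load_sam_generator(checkpoint, model_type, **amg_params)
    rgb = np.stack([image] * 3, axis=-1)
    raw = generator.generate(rgb)
    masks = []
    union = np.zeros(image.shape, dtype=bool)
    for record in raw:
        m = np.asarray(record["segmentation"], dtype=bool)
        if m.shape != image.shape:
            raise ValidationError(
                f"backend mask shape {m.shape} != image shape {image.shape}"
            )
        if m.any():
            masks.append(m)
            union |= m
    background = ~union
    if background.any():
        masks.append(background)
    out = MaskSet(masks=masks, provenance="sam").sort_by_area()
    if dedup_iou is not None:
        out = dedup_by_iou(out, dedup_iou)
    return out


def _load_sam_generator(checkpoint: str | None, model_type: str, **amg_params):
    try:
        import torch  # noqa: F401
        from segment_anything import SamAutomaticMaskGenerator, sam_model_registry
    except ImportError as exc:
        raise CapabilityError(
            "the 'sam' backend needs the optional dependencies "
            "segment-anything and torch (pip install idcc[sam])"
        ) from exc
    if checkpoint is None:
        raise CapabilityError("the 'sam' backend needs a model checkpoint path")
    sam = sam_model_registry[model_type](checkpoint=checkpoint)
    return SamAutomaticMaskGenerator(sam, **amg_params)


BACKENDS = {"reference": reference_backend, "sam": sam_backend}


def segment(image: np.ndarray, backend: str = "reference", **backend_params) -> MaskSet:
    """Run a named backend; returns an area-descending MaskSet.

    No prompt parameters exist: the mask-proposal pathway is prompt-free
    by construction.
    """
    if backend not in BACKENDS:
        raise CapabilityError(
            f"unknown backend {backend!r}; available: {sorted(BACKENDS)}"
        )
    return BACKENDS[backend](image, **backend_params)
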
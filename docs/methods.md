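# Methods

## Pipeline model

The package assumes fluorescence (or bright-field histology) images in
which individual cells are compact, roughly convex regions that differ in
intensity from their surroundings, and that a prompt-free instance
segmenter can propose one mask per cell plus one mask covering the
background. Counting is then purely geometric: one non-background mask =
one cell, located at the midpoint of the mask's bounding box. No model is
trained or fine-tuned anywhere in the pipeline.

## CLAHE

CLAHE is implemented directly rather than delegated to a library because
the exact clipping and normalization conventions are part of the package's
contract (library implementations — OpenCV, scikit-image — use different
clip-limit semantics and interpolation anchors, and would silently change
the mapping).

Parameters (all exposed in `ClaheParams` and on the CLI):

| parameter | default | units | role |
|---|---|---|---|
| `tile_size` | 8 | px | side of the square tiles (64-pixel neighborhoods) |
| `clip_limit` c | 0.8 | — | per-bin cap is `β = max(1, c·t²/L)` |
| `n_levels` L | 256 | — | histogram levels (256 for 8-bit input) |
| `p_min`, `p_max` | 0, 255 | intensity | output range endpoints |
| `g_min` | 0 | intensity | offset of the normalized range |

Numerical choices, made where no single published convention exists:

* **Clip convention.** `c` is a fraction of the uniform bin height
  `t²/L`, floored at one count so a mapping always exists. With the
  defaults (t = 8, L = 256) this is an aggressive β = 1, which pushes each
  tile toward a uniform (rank-like) mapping; the parameter is surfaced so
  other conventions can be emulated.
* **Excess redistribution** is single-pass and real-valued: the total
  excess E is added back as E/L to every bin, with no re-clipping.
  Because the cumulative mapping normalizes by the histogram sum, sum
  preservation (exact, checked to 1e-9) is the only property that matters.
* **Interpolation anchors** are tile centers; pixels outside the outermost
  centers clamp to the nearest tile row/column (the classical corner/edge
  rule). Interpolated values are rounded half-up, then clamped to
  `[g_min, p_max]`.
* **Non-divisible sizes** are reflect-padded on the bottom/right to tile
  multiples and cropped after remapping, so output shape always equals
  input shape.

Correctness is established against an independent per-pixel oracle
(`tests/_oracles.py`): plain-loop histograms, explicit cumulative sums,
scalar bilinear blending. The vectorized implementation must match it
bit-exactly on random images.

## Segmentation backends

The backend contract deliberately has no prompt inputs: mask proposal is
automatic, and the largest-area mask is treated as background (enforced by
an area-descending sort; `--no-skip-background` disables the skip for
backends that emit no background mask). Overlapping masks are not
deduplicated by default — one mask is one cell — but a greedy IoU
deduplication (`dedup_iou`) is available for experimentation.

The **reference backend** (Otsu threshold, polarity chosen so the
foreground is the minority class, 8-connected components, `min_area`
filter) exists so the whole pipeline is testable offline. It is a
single-threshold segmenter: it cannot split touching cells, and on images
where cells cover the majority of the frame the polarity heuristic can
invert. The **SAM adapter** wraps the pre-trained automatic mask generator
(optional extra; needs a checkpoint); its contract — background synthesis
as the complement of the instance union, area sorting, no prompts — is
tested with a stubbed generator, since exercising the real model requires
weights that are not shipped.

## Counting

Bounding-box width/height use the `max − min` convention (no +1), so
centers sit on the pixel-index midpoint, half a pixel off the pixel-area
centroid. This has no effect on counts — the only quantity evaluated — and
keeps the geometry identical to the published definition of the box.
Empty masks from degenerate backends are skipped with a logged warning
rather than aborting the image.

## Metrics

MAE and AAE are computed at full precision (display rounding only). The
AAE band is inclusive at |error| = T (default T = 10 cells), and the
density stratification assigns a true count of exactly 100 to the
low-density stratum. Empty strata are omitted from reports rather than
reported as zero.

## Synthetic generator

The generator emulates three benchmark regimes by their published summary
statistics — frame size, mean ± sd cells per image, and background
character — not by their texture:

* `idcia_like`: 800×600, 83 ± 104 cells, bright cells on a dark, unevenly
  illuminated field;
* `vgg_like`: 256×256, 174 ± 64 cells, small bright blobs;
* `adc_like`: 400×400 (the source regime does not state ROI dimensions;
  this is the package's choice), 165 ± 44 cells, bright field with darker
  cell rims.

Per-image counts are lognormal with moments matched to (mean, sd):
`σ² = ln(1 + (sd/mean)²)`, `μ = ln(mean) − σ²/2`, rounded and floored at
one cell. A lognormal is used instead of a truncated normal because one
regime's sd exceeds its mean (104 vs 83), making moment preservation under
truncation at zero impossible; with these parameters the mass below 0.5 is
negligible, so flooring does not bias the mean (verified empirically to
within 3 standard errors over 2,000 draws).

Cells are placed uniformly by rejection sampling with a minimum pairwise
separation (spatial clustering in real cultures is not modeled); if a
requested count cannot be placed within 10·n attempts the actual placed
count is recorded as truth, with a warning. Cells render as
Gaussian-shaded disks with an intensity floor at half peak (dark modes) or
as darker-rimmed regions (bright field); illumination unevenness is one
smooth sinusoidal wave of configurable amplitude, and pixel noise is
Gaussian. Geometry defaults (radius 3–8 px, peak intensity 180–255,
illumination amplitude 40) are the package's own choices.

All randomness derives from `(seed, image_index)` via independent seed
sequences, so datasets are bit-reproducible, including if images are
generated in parallel or out of order.

**What passing synthetic tests shows — and does not.** Exact recovery on
clean renders (MAE 0, AAE 100%) validates the plumbing: segmentation →
box → center → count → metrics, end to end. It does not certify accuracy
on real microscopy, where cells touch and overlap, illumination and focus
vary in ways one sinusoid does not capture, and segmentation quality —
not geometry — dominates the error. Counting accuracy on real data is
bounded by the chosen backend.

## Problem sizes

The test suite and the acceptance script run on deliberately modest sizes:
oracle comparisons on images up to 32×32 (the mapping logic is
size-independent), end-to-end recovery on 50 images of 256×256, and
2,000 count draws per profile for the moment checks. These sizes give
sub-pixel-exact or 3-standard-error resolution on every claim while
keeping the default run fast on a single CPU.

## Known limitations

* No splitting of merged or overlapping cells; backends that emit
  duplicate masks overcount unless `dedup_iou` is enabled.
* The reference backend is a single global threshold — it is a test
  harness and baseline, not a competitive segmenter.
* RGB input is collapsed to BT.601 luminance; per-channel processing is
  out of scope.
* No proprietary microscope formats (CZI, ND2) or OME-TIFF metadata.
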
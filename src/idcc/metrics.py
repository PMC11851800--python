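"""Counting-error metrics: MAE, acceptable absolute error (AAE), and
density-stratified reporting.

MAE = (1/N) * sum_i |C_i - Chat_i| over per-image true counts C_i and
predicted counts Chat_i.  AAE is the percentage of images whose absolute
count error is within a threshold T (inclusive at equality; default T=10
cells).  Reports are additionally stratified into low-density (true count
<= 100 cells, boundary inclusive) and high-density (> 100) images.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .exceptions import ValidationError


@dataclass(frozen=True)
class CountRecord:
    """One evaluated image: true count and predicted count."""

    image_id: str
    true_count: int
    predicted_count: int

    def __post_init__(self) -> None:
        if self.true_count < 0 or self.predicted_count < 0:
            raise ValidationError("counts must be non-negative")


@dataclass(frozen=True)
class EvalConfig:
    """AAE threshold T (cells) and the low/high density boundary (cells)."""

    aae_threshold: float = 10
    density_threshold: float = 100

    def __post_init__(self) -> None:
        if self.aae_threshold <= 0:
            raise ValidationError("aae_threshold must be > 0")
        if self.density_threshold <= 0:
            raise ValidationError("density_threshold must be > 0")


def mae(records: Sequence[CountRecord]) -> float:
    """Mean absolute error of the predicted counts, in cells."""
    if not records:
        raise ValidationError("MAE needs at least one record")
    return sum(abs(r.true_count - r.predicted_count) for r in records) / len(records)


def aae(records: Sequence[CountRecord], threshold: float = 10) -> float:
    """Percentage of images with |true - predicted| <= threshold (inclusive)."""
    if not records:
        raise ValidationError("AAE needs at least one record")
    if threshold <= 0:
        raise ValidationError("AAE threshold must be > 0")
    within = sum(abs(r.true_count - r.predicted_count) <= threshold for r in records)
    return 100.0 * within / len(records)


def stratified_report(
    records: Sequence[CountRecord], config: EvalConfig | None = None
) -> dict:
    """MAE/AAE overall and per density stratum.

    Returns a dict with keys ``overall`` and, when non-empty,
    ``low_density`` (true count <= density_threshold) and ``high_density``;
    each entry holds ``n_images``, ``mae`` and ``aae``.  Empty strata are
    absent from the report, not reported as zero.
    """
    if config is None:
        config = EvalConfig()
    if not records:
        raise ValidationError("report needs at least one record")

    def summarize(subset: Sequence[CountRecord]) -> dict:
        return {
            "n_images": len(subset),
            "mae": mae(subset),
            "aae": aae(subset, config.aae_threshold),
        }

    low = [r for r in records if r.true_count <= config.density_threshold]
    high = [r for r in records if r.true_count > config.density_threshold]
    report = {
        "aae_threshold": config.aae_threshold,
        "density_threshold": config.density_threshold,
        "overall": summarize(records),
    }
    if low:
        report["low_density"] = summarize(low)
    if high:
        report["high_density"] = summarize(high)
    return report


def format_report(report: dict) -> str:
    """Aligned-text rendering of a stratified report."""
    lines = [f"{'stratum':<14}{'n':>6}{'MAE':>10}{'AAE %':>10}"]
    for key in ("overall", "low_density", "high_density"):
        if key in report:
            s = report[key]
            lines.append(
                f"{key:<14}{s['n_images']:>6}{s['mae']:>10.2f}{s['aae']:>10.1f}"
            )
    return "\n".join(lines)
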
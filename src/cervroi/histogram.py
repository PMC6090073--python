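"""Intensity histograms and the first-quartile dynamic threshold.

Raw radiographs occupy image-specific slices of the container's gray
range (often only the darkest tenth of a 16-bit scale), so a single
fixed binarization cut cannot work across a set of images.  The dynamic
threshold adapts per image: after complementing, the background pixels
dominate the darkest quarter of the histogram, so the first quartile of
the cumulative distribution marks the background/object cut.
"""

from __future__ import annotations

import csv
import dataclasses
import math
from pathlib import Path

import numpy as np

from .io import GrayImage

__all__ = [
    "IntensityHistogram",
    "compute_histogram",
    "cumulative",
    "quartile_threshold",
    "dynamic_range",
    "write_histogram_csv",
]


@dataclasses.dataclass(frozen=True)
class IntensityHistogram:
    """Per-gray-level pixel counts over the full container range.

    ``counts[g]`` is the number of pixels at level ``g`` (dense over
    ``0 .. 2**bit_depth - 1``); ``total`` equals the source pixel count.
    The same type carries the cumulative form, where ``counts[g]`` is
    the number of pixels at levels ``<= g`` and ``is_cumulative`` is set.
    """

    counts: np.ndarray
    total: int
    bit_depth: int
    is_cumulative: bool = False

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.ndim != 1 or len(c) != (1 << self.bit_depth):
            raise ValueError(
                f"counts must have 2**{self.bit_depth} entries, got {c.shape}"
            )
        if (c < 0).any():
            raise ValueError("negative histogram count")
        object.__setattr__(self, "counts", c)
        check = c[-1] if self.is_cumulative else int(c.sum())
        if check != self.total:
            raise ValueError(f"histogram does not conserve pixels: {check} != {self.total}")

    def as_sparse(self) -> dict[int, int]:
        """Nonzero bins as ``{level: count}`` for compact reporting."""
        (levels,) = np.nonzero(self.counts)
        return {int(g): int(self.counts[g]) for g in levels}


def compute_histogram(img: GrayImage) -> IntensityHistogram:
    """Count pixels per gray level over the image's full depth range."""
    counts = np.bincount(img.pixels.ravel(), minlength=1 << img.bit_depth)
    return IntensityHistogram(
        counts=counts, total=img.rows * img.cols, bit_depth=img.bit_depth
    )


def cumulative(h: IntensityHistogram) -> IntensityHistogram:
    """Running sum of the histogram; the last entry equals ``total``."""
    if h.is_cumulative:
        return h
    return IntensityHistogram(
        counts=np.cumsum(h.counts),
        total=h.total,
        bit_depth=h.bit_depth,
        is_cumulative=True,
    )


def quartile_threshold(h: IntensityHistogram, fraction: float = 0.25) -> int:
    """Smallest gray level whose cumulative count reaches ``ceil(fraction * N)``.

    With the default ``fraction = 0.25`` this is the empirical first
    quartile of the pixel intensities: at least a quarter of the pixels
    lie at or below the returned level.  On a complemented radiograph
    those pixels are background, so binarizing strictly above this level
    leaves the background at 0.

    Ties and plateaus resolve to the smallest qualifying level, making
    the cut deterministic.

    Raises
    ------
    ValueError
        Empty histogram, or ``fraction`` outside the open interval (0, 1).
    """
    if h.total <= 0:
        raise ValueError("cannot threshold an empty histogram")
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must lie strictly in (0, 1), got {fraction}")
    target = math.ceil(fraction * h.total)
    cum = h.counts if h.is_cumulative else np.cumsum(h.counts)
    return int(np.searchsorted(cum, target, side="left"))


def dynamic_range(img: GrayImage) -> tuple[int, int]:
    """Occupied gray-level range ``(min, max)`` of the raster.

    Raw radiographs typically occupy a small, image-specific slice of
    the container depth; this pair feeds the diagnostics report.
    """
    px = img.pixels
    return int(px.min()), int(px.max())


def write_histogram_csv(h: IntensityHistogram, path: str | Path) -> None:
    """Export nonzero bins as two-column CSV ``(level, count)``."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["level", "count"])
        for level, count in h.as_sparse().items():
            writer.writerow([level, count])
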
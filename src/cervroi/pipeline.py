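"""The full ROI-extraction pipeline and its diagnostics.

The stages run in a fixed order on each radiograph:

1.  complement the raster (digital-X-ray convention → film convention),
2.  histogram + first-quartile dynamic threshold,
3.  binarize; label components; keep the largest (the silhouette),
4.  boundary scan per half-image around the silhouette centroid column,
5.  full-height crop of the complement image to the neck span,
6.  histogram equalization of the cropped region onto the full depth
    range.

The crop typically removes 30–60 % of the pixels while keeping the
cervical vertebrae, and the equalization stretches the ROI's narrow
occupied gray range onto the whole container scale.
"""

from __future__ import annotations

import csv
import dataclasses
import logging
import time
from pathlib import Path
from typing import Iterable

import numpy as np

from .bounds import RoiBounds, detect_bounds
from .histogram import compute_histogram, dynamic_range, quartile_threshold
from .io import GrayImage, complement
from .mask import binarize, isolate_object, label_objects, largest_object

__all__ = [
    "PipelineOptions",
    "PipelineResult",
    "crop",
    "reduction_percent",
    "equalize",
    "run_pipeline",
    "diagnostics_report",
]

logger = logging.getLogger("cervroi")


@dataclasses.dataclass(frozen=True)
class PipelineOptions:
    """Tunable pipeline settings.

    The defaults reproduce the reference method exactly: first-quartile
    (0.25) dynamic threshold, complement applied, full-height crop.
    """

    fraction: float = 0.25
    apply_complement: bool = True
    output_format: str = "png"
    sidecar: str | None = None
    verbosity: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction < 1.0:
            raise ValueError(
                f"threshold fraction must lie strictly in (0, 1), got {self.fraction}"
            )


@dataclasses.dataclass(frozen=True)
class PipelineResult:
    """Everything a run produces: the enhanced ROI plus diagnostics."""

    roi_image: GrayImage
    bounds: RoiBounds
    threshold: int
    reduction_percent: float
    input_range: tuple[int, int]
    roi_range_before_eq: tuple[int, int]

    def __post_init__(self) -> None:
        if not 0.0 <= self.reduction_percent < 100.0:
            raise ValueError(f"reduction percent {self.reduction_percent} out of range")
        if (self.roi_image.rows, self.roi_image.cols) != (
            self.bounds.height,
            self.bounds.width,
        ):
            raise ValueError("ROI dimensions disagree with bounds")


def crop(img: GrayImage, b: RoiBounds) -> GrayImage:
    """Extract the inclusive rectangle ``b`` from ``img``."""
    if b.bottom_row > img.rows - 1 or b.right_col > img.cols - 1:
        raise ValueError(
            f"bounds {b.as_dict()} exceed image {img.rows}x{img.cols}"
        )
    sub = img.pixels[b.top_row : b.bottom_row + 1, b.left_col : b.right_col + 1]
    return GrayImage(pixels=sub.copy(), bit_depth=img.bit_depth)


def reduction_percent(original: GrayImage, roi: GrayImage) -> float:
    """Pixel-count reduction ``100 * (1 - roi / original)`` in percent."""
    if roi.rows > original.rows or roi.cols > original.cols:
        raise ValueError("ROI larger than the original image")
    n_orig = original.rows * original.cols
    n_roi = roi.rows * roi.cols
    return 100.0 * (1.0 - n_roi / n_orig)


def equalize(img: GrayImage) -> GrayImage:
    """Histogram equalization onto the full ``[0, 2**bit_depth - 1]`` range.

    Standard cumulative-distribution remapping with the minimum-CDF
    normalization::

        out(g) = round((cdf(g) - cdf_min) / (N - cdf_min) * (2**d - 1))

    where ``cdf_min`` is the smallest nonzero cumulative count.  The
    mapping is monotone non-decreasing, and any input with at least two
    distinct levels comes out spanning the exact full range — the
    darkest occupied level maps to 0 and the brightest to the container
    maximum.  A constant image has no defined mapping and is returned
    unchanged (with a warning).
    """
    hist = compute_histogram(img)
    cdf = np.cumsum(hist.counts)
    nonzero = cdf[cdf > 0]
    cdf_min = int(nonzero[0])
    n = hist.total
    if n == cdf_min:  # single occupied level: degenerate, nothing to stretch
        logger.warning("constant ROI: equalization skipped")
        return img
    top = img.max_level
    lut = np.rint((cdf - cdf_min) / (n - cdf_min) * top)
    lut = np.clip(lut, 0, top).astype(img.pixels.dtype)
    return GrayImage(pixels=lut[img.pixels], bit_depth=img.bit_depth)


def run_pipeline(img: GrayImage, options: PipelineOptions | None = None) -> PipelineResult:
    """Run every stage on one radiograph and return the enhanced ROI.

    Deterministic: the same input raster and options always produce the
    same output bytes.  The crop and the equalization operate on the
    complement image (or the raw input under ``apply_complement=False``).

    Raises
    ------
    NoSilhouetteError
        Thresholding yielded no foreground object (e.g. a blank image).
    NoNeckError
        The silhouette has no detectable narrow span.
    """
    options = options or PipelineOptions()
    t0 = time.perf_counter()
    input_range = dynamic_range(img)

    work = complement(img) if options.apply_complement else img
    _log_stage("complement", t0)

    hist = compute_histogram(work)
    threshold = quartile_threshold(hist, options.fraction)
    logger.info("dynamic threshold (fraction %.2f): %d", options.fraction, threshold)
    _log_stage("threshold", t0)

    mask = binarize(work, threshold)
    objs = label_objects(mask)
    silhouette_obj = largest_object(objs)
    silhouette = isolate_object(mask, silhouette_obj)
    _log_stage("silhouette", t0)

    m_c = int(np.floor(silhouette_obj.centroid_col + 0.5))
    bounds = detect_bounds(silhouette, m_c)
    _log_stage("bounds", t0)

    roi = crop(work, bounds)
    roi_range = dynamic_range(roi)
    enhanced = equalize(roi)
    _log_stage("equalize", t0)

    return PipelineResult(
        roi_image=enhanced,
        bounds=bounds,
        threshold=threshold,
        reduction_percent=reduction_percent(img, roi),
        input_range=input_range,
        roi_range_before_eq=roi_range,
    )


def _log_stage(name: str, t0: float) -> None:
    logger.debug("stage %-10s at %7.1f ms", name, (time.perf_counter() - t0) * 1e3)


_REPORT_COLUMNS = [
    "input_min",
    "input_max",
    "reduction_percent",
    "threshold",
    "top",
    "bottom",
    "left",
    "right",
]


def diagnostics_report(
    results: Iterable[PipelineResult], path: str | Path | None = None
) -> list[dict[str, float]]:
    """Per-image diagnostics table: dynamic range, reduction, threshold, bounds.

    Mirrors the scatter-style reporting used to characterize a set of
    radiographs (occupied gray range per image, percent reduction per
    image).  Returns the rows; writes CSV when ``path`` is given.
    """
    rows = []
    for r in results:
        rows.append(
            {
                "input_min": r.input_range[0],
                "input_max": r.input_range[1],
                "reduction_percent": round(r.reduction_percent, 4),
                "threshold": r.threshold,
                **r.bounds.as_dict(),
            }
        )
    if not rows:
        raise ValueError("diagnostics report needs at least one result")
    if path is not None:
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=_REPORT_COLUMNS)
            writer.writeheader()
            writer.writerows(rows)
    return rows
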
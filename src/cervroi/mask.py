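"""Binarization and connected-object extraction.

Thresholding the complement image turns dense anatomy into a closed
foreground object against a zero background.  The largest 8-connected
component is the patient silhouette; every other blob (markers, labels,
collimator edges) is noise and is removed before the boundary scan, so
stray objects cannot corrupt the neck detection.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .io import GrayImage

__all__ = [
    "BinaryMask",
    "ObjectFeatures",
    "NoSilhouetteError",
    "binarize",
    "label_objects",
    "largest_object",
    "isolate_object",
    "save_mask_png",
]

# 8-connectivity: diagonal neighbours belong to the same component.
_STRUCTURE_8 = np.ones((3, 3), dtype=bool)


class NoSilhouetteError(RuntimeError):
    """Thresholding produced no foreground object at all."""


@dataclasses.dataclass(frozen=True)
class BinaryMask:
    """2-D {0, 1} raster; 1 = object, 0 = background."""

    cells: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.cells)
        if c.ndim != 2:
            raise ValueError(f"mask must be 2-D, got {c.ndim}-D")
        if not np.isin(c, (0, 1)).all():
            raise ValueError("mask cells must be 0 or 1")
        object.__setattr__(self, "cells", c.astype(np.uint8, copy=False))

    @property
    def rows(self) -> int:
        return self.cells.shape[0]

    @property
    def cols(self) -> int:
        return self.cells.shape[1]


@dataclasses.dataclass(frozen=True)
class ObjectFeatures:
    """Connected-component descriptor: area, centroid and bounding box.

    ``bbox`` is ``(top, left, bottom, right)``, inclusive on all sides,
    0-based.
    """

    label: int
    area: int
    centroid_row: float
    centroid_col: float
    bbox: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if self.area < 1:
            raise ValueError("component area must be >= 1")
        top, left, bottom, right = self.bbox
        if not (top <= self.centroid_row <= bottom and left <= self.centroid_col <= right):
            raise ValueError("bbox must contain the centroid")


def binarize(img: GrayImage, t: int) -> BinaryMask:
    """Threshold: cell = 1 where pixel > ``t`` (strictly), else 0.

    The strict inequality guarantees that with the first-quartile cut on
    the complement image the darkest quarter of pixels — the background —
    maps to 0, which the zero-counting boundary scan requires.
    """
    if not 0 <= t <= img.max_level:
        raise ValueError(f"threshold {t} outside [0, {img.max_level}]")
    return BinaryMask(cells=(img.pixels > t).astype(np.uint8))


def label_objects(mask: BinaryMask) -> list[ObjectFeatures]:
    """Describe every 8-connected component of 1-cells.

    Returns one :class:`ObjectFeatures` per component (empty list for an
    all-zero mask).  Component areas sum to the mask's 1-count, and
    centroids are per-component pixel-coordinate means.
    """
    labeled, n = ndimage.label(mask.cells, structure=_STRUCTURE_8)
    if n == 0:
        return []
    index = np.arange(1, n + 1)
    areas = ndimage.sum_labels(mask.cells, labeled, index)
    centroids = ndimage.center_of_mass(mask.cells, labeled, index)
    slices = ndimage.find_objects(labeled)
    out = []
    for lab, area, (cr, cc), slc in zip(index, areas, centroids, slices):
        out.append(
            ObjectFeatures(
                label=int(lab),
                area=int(area),
                centroid_row=float(cr),
                centroid_col=float(cc),
                bbox=(slc[0].start, slc[1].start, slc[0].stop - 1, slc[1].stop - 1),
            )
        )
    return out


def largest_object(objs: list[ObjectFeatures]) -> ObjectFeatures:
    """The component with maximum area — assumed to be the silhouette.

    Ties break on smallest ``(top, left)`` bbox corner, then smallest
    label, so selection is deterministic.

    Raises
    ------
    NoSilhouetteError
        Empty component list (the threshold produced no object).
    """
    if not objs:
        raise NoSilhouetteError("no foreground object found after thresholding")
    return min(objs, key=lambda o: (-o.area, o.bbox[0], o.bbox[1], o.label))


def isolate_object(mask: BinaryMask, obj: ObjectFeatures) -> BinaryMask:
    """Zero every component except ``obj``'s, leaving the silhouette alone.

    Raises
    ------
    ValueError
        ``obj`` does not correspond to a component of this mask.
    """
    labeled, n = ndimage.label(mask.cells, structure=_STRUCTURE_8)
    if not 1 <= obj.label <= n:
        raise ValueError(f"object label {obj.label} absent from mask ({n} components)")
    kept = (labeled == obj.label).astype(np.uint8)
    if int(kept.sum()) != obj.area:
        raise ValueError(
            f"stale object: label {obj.label} has area {int(kept.sum())}, "
            f"expected {obj.area}"
        )
    return BinaryMask(cells=kept)


def save_mask_png(mask: BinaryMask, path) -> None:
    """Write the mask as a 0/255 PNG for visual inspection."""
    from PIL import Image

    Image.fromarray(mask.cells * np.uint8(255), mode="L").save(path, format="PNG")
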
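"""Grayscale radiograph I/O and the image complement.

Radiographs arrive as single-frame grayscale rasters in DICOM, PNG or
TIFF containers at 8- or 16-bit depth.  Loading keeps the pixel raster
only: DICOM patient and acquisition metadata are discarded at read time
and the in-memory type has no slot that could carry them.

Digital X-ray detectors receive *less* signal behind dense anatomy, so
bone appears dark — the opposite of film.  The complement

    C(i, j) = max(A) - A(i, j)

restores the film convention (dense = bright) and anchors every image's
histogram at gray level 0, which the downstream quartile threshold
relies on.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

__all__ = [
    "GrayImage",
    "UnsupportedImageError",
    "DepthError",
    "load_grayscale",
    "complement",
    "save_image",
]


class UnsupportedImageError(ValueError):
    """Input is not a single-frame grayscale raster we can handle."""


class DepthError(ValueError):
    """Pixel values do not fit the requested container depth."""


@dataclasses.dataclass(frozen=True)
class GrayImage:
    """A 2-D non-negative integer intensity raster with a declared bit depth.

    Parameters
    ----------
    pixels
        2-D integer array, row-major.  Stored as ``uint8`` or ``uint16``
        according to ``bit_depth``.
    bit_depth
        Container depth, 8 or 16.  Inferred from the source container,
        never from the observed maximum, so dark images keep their depth.
    """

    pixels: np.ndarray
    bit_depth: int

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise UnsupportedImageError(f"expected a 2-D raster, got {px.ndim}-D")
        if px.shape[0] < 2 or px.shape[1] < 2:
            raise UnsupportedImageError(f"raster too small: {px.shape}")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if not np.issubdtype(px.dtype, np.integer):
            raise ValueError(f"pixels must be integer, got dtype {px.dtype}")
        if px.min() < 0 or px.max() > self.max_level:
            raise ValueError(
                f"pixel values outside [0, {self.max_level}] for {self.bit_depth}-bit"
            )
        dtype = np.uint8 if self.bit_depth == 8 else np.uint16
        object.__setattr__(self, "pixels", px.astype(dtype, copy=False))

    @property
    def rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def cols(self) -> int:
        return self.pixels.shape[1]

    @property
    def max_level(self) -> int:
        """Largest representable gray level, ``2**bit_depth - 1``."""
        return (1 << self.bit_depth) - 1


def _from_array(arr: np.ndarray, source: str) -> GrayImage:
    """Build a GrayImage from a decoded container array, inferring depth."""
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        raise UnsupportedImageError(f"{source}: color image (shape {arr.shape})")
    if arr.ndim != 2:
        raise UnsupportedImageError(
            f"{source}: expected single-frame 2-D raster, got shape {arr.shape}"
        )
    if not np.issubdtype(arr.dtype, np.integer):
        raise UnsupportedImageError(f"{source}: non-integer pixel type {arr.dtype}")
    # Depth from the stored sample width, not the observed max.
    bit_depth = 8 if arr.dtype.itemsize <= 1 else 16
    return GrayImage(pixels=arr, bit_depth=bit_depth)


def _load_dicom(path: Path) -> GrayImage:
    import pydicom

    ds = pydicom.dcmread(path)
    if int(getattr(ds, "SamplesPerPixel", 1)) != 1:
        raise UnsupportedImageError(f"{path}: DICOM is not grayscale")
    if int(getattr(ds, "NumberOfFrames", 1)) != 1:
        raise UnsupportedImageError(f"{path}: multi-frame DICOM")
    arr = ds.pixel_array  # pixel data only; the dataset object is dropped here
    bits = int(getattr(ds, "BitsStored", getattr(ds, "BitsAllocated", 16)))
    depth = 8 if bits <= 8 else 16
    return GrayImage(pixels=np.asarray(arr), bit_depth=depth)


def load_grayscale(path: str | Path, fmt: str | None = None) -> GrayImage:
    """Load a single-frame grayscale radiograph, discarding all metadata.

    Parameters
    ----------
    path
        Source file (DICOM, PNG or TIFF).
    fmt
        Optional explicit format tag (``"dicom"``, ``"png"``, ``"tiff"``);
        by default the file suffix decides.

    Returns
    -------
    GrayImage
        Pixel raster only.  The returned type has no metadata slot, so no
        patient or acquisition information can survive the load.

    Raises
    ------
    FileNotFoundError
        Missing input file.
    UnsupportedImageError
        Color, multi-frame or otherwise unreadable input.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"no such image file: {path}")
    tag = (fmt or path.suffix.lstrip(".")).lower()
    if tag in ("dcm", "dicom", "ima"):
        return _load_dicom(path)
    if tag in ("tif", "tiff"):
        import tifffile

        return _from_array(tifffile.imread(path), str(path))
    if tag == "png":
        from PIL import Image

        with Image.open(path) as im:
            if im.mode in ("RGB", "RGBA", "P"):
                raise UnsupportedImageError(f"{path}: color PNG (mode {im.mode})")
            return _from_array(np.asarray(im), str(path))
    # Unknown suffix: let pydicom have a try (DICOM files often lack one),
    # then fall back to generic decoding.
    try:
        return _load_dicom(path)
    except Exception:
        pass
    import imageio.v3 as iio

    return _from_array(iio.imread(path), str(path))


def complement(img: GrayImage) -> GrayImage:
    """Return the image complement ``C(i,j) = max(A) - A(i,j)``.

    The complement flips digital-X-ray convention (dense anatomy dark)
    to film convention (dense bright) and, because it subtracts from the
    observed maximum, forces the output minimum to exactly 0 — every
    complemented histogram starts at the origin.
    """
    px = img.pixels.astype(np.int64)
    out = px.max() - px
    return GrayImage(pixels=out, bit_depth=img.bit_depth)


def save_image(img: GrayImage, path: str | Path, fmt: str | None = None) -> None:
    """Write the raster losslessly as PNG (8-bit) or TIFF (8/16-bit).

    Raises
    ------
    DepthError
        A 16-bit raster requested in an 8-bit-only container.
    OSError
        Unwritable destination.
    """
    path = Path(path)
    tag = (fmt or path.suffix.lstrip(".")).lower()
    if tag == "png":
        from PIL import Image

        # PNG is the 8-bit container here; 16-bit rasters go to TIFF.
        require_depth(img, 8)
        Image.fromarray(img.pixels, mode="L").save(path, format="PNG")
    elif tag in ("tif", "tiff"):
        import tifffile

        tifffile.imwrite(path, img.pixels)
    else:
        raise ValueError(f"unsupported output format: {tag!r} (use png or tiff)")


def require_depth(img: GrayImage, bit_depth: int) -> None:
    """Raise :class:`DepthError` unless ``img`` fits an ``bit_depth``-bit container."""
    if img.bit_depth > bit_depth:
        raise DepthError(
            f"{img.bit_depth}-bit raster does not fit an {bit_depth}-bit container"
        )
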
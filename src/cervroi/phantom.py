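"""Synthetic neck phantoms with ground-truth geometry.

A phantom emulates the features of a frontal/lateral cervical
radiograph that the ROI method relies on: a head truncated by the top
edge of the frame, a narrow vertical neck, and a shoulder slab running
to the bottom edge, rendered in digital-X-ray convention (dense anatomy
at LOW gray values, background at HIGH values).  Intensity uses four
bands — bone core, soft tissue, a low-density outer neck margin, and
background — plus additive clipped Gaussian noise.  The outer margin
matters: it is what a too-high threshold strips away, shrinking the
silhouette into the denser neck and over-cropping the ROI, the known
failure mode of raising the quartile fraction.

The generator returns the neck band's outer columns as ground truth, so
boundary detection can be scored in pixels without clinical data.
Geometry is axis-aligned (vertical patient axis), matching the method's
own assumption, and every phantom is reproducible from its spec.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np

from .io import GrayImage

__all__ = ["PhantomSpec", "generate_phantom", "generate_suite", "write_phantom"]


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity parameters of one synthetic radiograph.

    Geometric fields are fractions of the image dimensions and intensity
    fields fractions of the full depth range, so one spec renders
    consistently at 8 and 16 bit.

    The default neck half-width (0.20) makes the neck span 40 % of the
    image width, so the full-height crop removes about 60 % of the
    pixels; the suite generator varies this to cover the 30–60 %
    reduction range.  Noise at 2 % of the depth range keeps the
    intensity bands separable by a first-quartile cut, reflecting how
    strongly background dominates the dark end of a complemented
    radiograph.
    """

    rows: int = 512
    cols: int = 512
    head_radius_frac: float = 0.36
    neck_halfwidth_frac: float = 0.20
    shoulder_halfwidth_frac: float = 0.40
    neck_top_frac: float = 0.10
    neck_bottom_frac: float = 0.62
    bone_level_frac: float = 0.85
    tissue_level_frac: float = 0.55
    margin_level_frac: float = 0.25
    margin_width_frac: float = 0.20  # of the neck half-width, each side
    background_level_frac: float = 0.06
    noise_sd_frac: float = 0.02
    bit_depth: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if not (
            self.neck_halfwidth_frac < self.shoulder_halfwidth_frac
            and self.neck_halfwidth_frac < self.head_radius_frac
        ):
            raise ValueError(
                "the neck must be the narrowest span: neck_halfwidth_frac "
                "must be below both shoulder_halfwidth_frac and head_radius_frac"
            )
        if not (
            0.0
            <= self.background_level_frac
            < self.margin_level_frac
            < self.tissue_level_frac
            < self.bone_level_frac
            <= 1.0
        ):
            raise ValueError(
                "intensity bands must satisfy background < margin < tissue <= bone"
            )
        if not 0.0 < self.neck_top_frac < self.neck_bottom_frac < 1.0:
            raise ValueError("neck row band must satisfy 0 < top < bottom < 1")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        # The head chord must still exceed the neck width where the neck
        # band starts, or rows above the neck would be narrower than the
        # neck and steal the narrowest-row selection.
        head_r = self.head_radius_frac * self.cols
        r0 = self.neck_top_frac * self.rows
        if head_r <= r0 or math.sqrt(head_r**2 - r0**2) <= self.neck_halfwidth_frac * self.cols:
            raise ValueError(
                "head too small for this neck: it must remain wider than the "
                "neck down to the neck band's top row"
            )


def generate_phantom(spec: PhantomSpec) -> tuple[GrayImage, tuple[int, int]]:
    """Render one phantom and its ground-truth neck columns ``(a, b)``.

    ``(a, b)`` are the outermost columns of the neck band (including its
    low-density margin), inclusive.  The silhouette touches the top and
    bottom frame edges — as a clinical frame does — so every row
    intersects the object and the boundary scan is well posed.
    """
    rows, cols, depth = spec.rows, spec.cols, spec.bit_depth
    top = (1 << depth) - 1
    rng = np.random.default_rng(spec.seed)

    # Density map in film convention (dense = bright); complemented at the end.
    dense = np.full((rows, cols), spec.background_level_frac, dtype=np.float64)
    rr, cc = np.mgrid[0:rows, 0:cols]
    cx = (cols - 1) / 2.0

    # Head: disc centered on the top edge, truncated by the frame.
    head_r = spec.head_radius_frac * cols
    head = rr**2 + (cc - cx) ** 2 <= head_r**2
    dense[head] = spec.tissue_level_frac

    neck_hw = spec.neck_halfwidth_frac * cols
    a = int(math.ceil(cx - neck_hw))
    b = int(math.floor(cx + neck_hw))
    r0 = int(round(spec.neck_top_frac * rows))
    r1 = int(round(spec.neck_bottom_frac * rows))

    # Neck band: low-density outer margin, tissue, bone core.
    dense[r0 : r1 + 1, a : b + 1] = spec.margin_level_frac
    margin = max(1, int(round(spec.margin_width_frac * neck_hw)))
    dense[r0 : r1 + 1, a + margin : b - margin + 1] = spec.tissue_level_frac
    core_hw = max(1, int(round(0.35 * neck_hw)))
    c0, c1 = int(round(cx)) - core_hw, int(round(cx)) + core_hw
    dense[r0 : r1 + 1, c0 : c1 + 1] = spec.bone_level_frac

    # Shoulder slab from below the neck band to the bottom edge.
    sh_hw = spec.shoulder_halfwidth_frac * cols
    shoulders = (rr > r1) & (np.abs(cc - cx) <= sh_hw)
    dense[shoulders] = spec.tissue_level_frac

    noisy = dense + rng.normal(0.0, spec.noise_sd_frac, size=dense.shape)
    film = np.rint(np.clip(noisy, 0.0, 1.0) * top)
    detector = top - film  # dense = dark, as the digital detector sees it
    img = GrayImage(pixels=detector.astype(np.int64), bit_depth=depth)
    return img, (a, b)


def generate_suite(
    n: int,
    seed: int,
    bit_depths: tuple[int, ...] = (8,),
    rows: int = 512,
    cols: int = 512,
) -> list[tuple[GrayImage, tuple[int, int]]]:
    """Seeded suite of ``n`` phantoms per requested bit depth.

    Neck half-widths are sampled uniformly over fractions 0.21–0.33 of
    the image width, so full-height crops remove between roughly 30 %
    and 60 % of the pixels across the suite — the reduction range the
    method is characterized by.  Matched geometry is reused across bit
    depths (phantom *i* has an identical layout and noise pattern at 8
    and 16 bit), enabling cross-depth comparisons.
    """
    if n < 1:
        raise ValueError("suite size must be >= 1")
    rng = np.random.default_rng(seed)
    halfwidths = rng.uniform(0.21, 0.33, size=n)
    phantom_seeds = rng.integers(0, 2**31 - 1, size=n)
    out = []
    for hw, ps in zip(halfwidths, phantom_seeds):
        for depth in bit_depths:
            spec = PhantomSpec(
                rows=rows,
                cols=cols,
                neck_halfwidth_frac=float(hw),
                bit_depth=int(depth),
                seed=int(ps),
            )
            out.append(generate_phantom(spec))
    return out


def write_phantom(
    img: GrayImage, truth: tuple[int, int], out_dir: str | Path, stem: str
) -> tuple[Path, Path]:
    """Write a phantom image plus its JSON ground-truth sidecar.

    8-bit phantoms go to PNG, 16-bit to TIFF.  Returns both paths.
    """
    from .io import save_image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = "png" if img.bit_depth == 8 else "tiff"
    img_path = out_dir / f"{stem}.{ext}"
    save_image(img, img_path)
    meta_path = out_dir / f"{stem}.json"
    meta_path.write_text(
        json.dumps(
            {
                "neck_left_col": truth[0],
                "neck_right_col": truth[1],
                "rows": img.rows,
                "cols": img.cols,
                "bit_depth": img.bit_depth,
            },
            indent=2,
        )
    )
    return img_path, meta_path
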
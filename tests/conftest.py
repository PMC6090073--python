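import numpy as np
import pytest

from cervroi import GrayImage, BinaryMask
from cervroi.phantom import PhantomSpec, generate_phantom, generate_suite


@pytest.fixture(scope="session")
def default_phantom():
    """One 512x512 8-bit phantom with ground-truth neck columns."""
    return generate_phantom(PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def suite8():
    """The default 10-phantom 8-bit suite (seed 7)."""
    return generate_suite(10, seed=7, bit_depths=(8,))


def random_gray(rng: np.random.Generator, rows=12, cols=15, bit_depth=8) -> GrayImage:
    top = (1 << bit_depth) - 1
    return GrayImage(
        pixels=rng.integers(0, top + 1, size=(rows, cols)), bit_depth=bit_depth
    )


def random_single_component_mask(
    rng: np.random.Generator, rows=8, cols=12
) -> BinaryMask:
    """A mask holding one connected blob built from overlapping row runs.

    Each row carries a contiguous run whose center random-walks by at
    most one column per row and whose half-width is at least one, so
    consecutive runs always intersect and the blob is 4-connected.  The
    outermost columns stay background.
    """
    cells = np.zeros((rows, cols), dtype=np.uint8)
    center = int(rng.integers(3, cols - 3))
    for r in range(rows):
        center = int(np.clip(center + rng.integers(-1, 2), 2, cols - 3))
        half = int(rng.integers(1, 3))
        lo, hi = max(1, center - half), min(cols - 2, center + half)
        cells[r, lo : hi + 1] = 1
    return BinaryMask(cells=cells)
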
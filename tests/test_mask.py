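"""Binarization and connected-component extraction."""

import numpy as np
import pytest

from cervroi import (
    BinaryMask,
    GrayImage,
    NoSilhouetteError,
    binarize,
    isolate_object,
    label_objects,
    largest_object,
)


def flood_fill_components(cells: np.ndarray) -> list[set]:
    """Brute-force 8-connected components, independent of scipy."""
    rows, cols = cells.shape
    seen = np.zeros_like(cells, dtype=bool)
    comps = []
    for r in range(rows):
        for c in range(cols):
            if cells[r, c] == 1 and not seen[r, c]:
                stack, comp = [(r, c)], set()
                seen[r, c] = True
                while stack:
                    rr, cc = stack.pop()
                    comp.add((rr, cc))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            nr, nc = rr + dr, cc + dc
                            if (
                                0 <= nr < rows
                                and 0 <= nc < cols
                                and cells[nr, nc] == 1
                                and not seen[nr, nc]
                            ):
                                seen[nr, nc] = True
                                stack.append((nr, nc))
                comps.append(comp)
    return comps


@pytest.mark.parametrize(
    "pixels, t, expected",
    [
        ([[0, 10], [5, 200]], 10, [[0, 0], [0, 1]]),  # strictly greater
        ([[0, 1], [1, 0]], 0, [[0, 1], [1, 0]]),
    ],
)
def test_binarize_strict_greater_rule(pixels, t, expected):
    img = GrayImage(pixels=np.array(pixels), bit_depth=8)
    np.testing.assert_array_equal(binarize(img, t).cells, np.array(expected))


def test_binarize_at_max_gives_empty_mask_and_count_monotone():
    rng = np.random.default_rng(2)
    img = GrayImage(pixels=rng.integers(0, 256, size=(9, 9)), bit_depth=8)
    assert binarize(img, int(img.pixels.max())).cells.sum() == 0
    counts = [binarize(img, t).cells.sum() for t in range(0, 256, 16)]
    assert counts == sorted(counts, reverse=True)


def test_label_single_block():
    cells = np.zeros((5, 5), dtype=np.uint8)
    cells[1:4, 1:4] = 1
    (obj,) = label_objects(BinaryMask(cells=cells))
    assert obj.area == 9
    assert (obj.centroid_row, obj.centroid_col) == (2.0, 2.0)
    assert obj.bbox == (1, 1, 3, 3)


def test_diagonal_pixels_are_one_component():
    cells = np.zeros((4, 4), dtype=np.uint8)
    cells[1, 1] = cells[2, 2] = 1
    objs = label_objects(BinaryMask(cells=cells))
    assert len(objs) == 1 and objs[0].area == 2


def test_empty_mask_yields_no_objects_and_largest_raises():
    objs = label_objects(BinaryMask(cells=np.zeros((4, 4), dtype=np.uint8)))
    assert objs == []
    with pytest.raises(NoSilhouetteError):
        largest_object(objs)


def test_labeling_matches_flood_fill_oracle_on_random_masks():
    rng = np.random.default_rng(23)
    for _ in range(40):
        cells = (rng.random((rng.integers(5, 20), rng.integers(5, 20))) < 0.4).astype(np.uint8)
        mask = BinaryMask(cells=cells)
        objs = label_objects(mask)
        oracle = flood_fill_components(cells)
        assert len(objs) == len(oracle)
        assert sum(o.area for o in objs) == int(cells.sum())
        oracle_feats = set()
        for comp in oracle:
            rs = [p[0] for p in comp]
            cs = [p[1] for p in comp]
            oracle_feats.add(
                (len(comp), min(rs), min(cs), max(rs), max(cs),
                 round(sum(rs) / len(rs), 9), round(sum(cs) / len(cs), 9))
            )
        got = {
            (o.area, *o.bbox, round(o.centroid_row, 9), round(o.centroid_col, 9))
            for o in objs
        }
        assert got == oracle_feats


def test_largest_object_selection_and_tie_rule():
    def obj_at(top, area_side):
        cells = np.zeros((12, 12), dtype=np.uint8)
        cells[top : top + area_side, 1 : 1 + area_side] = 1
        return cells

    cells = obj_at(0, 2) | 0
    cells[5:8, 5:8] = 1  # area 9
    cells[10:11, 10:12] = 1  # area 2
    objs = label_objects(BinaryMask(cells=cells))
    assert largest_object(objs).area == 9

    # Equal areas: the object whose bbox top is smallest wins.
    tie = np.zeros((12, 12), dtype=np.uint8)
    tie[0:2, 0:2] = 1
    tie[5:7, 5:7] = 1
    winner = largest_object(label_objects(BinaryMask(cells=tie)))
    assert winner.bbox[0] == 0


def test_isolate_erases_other_blobs_and_conserves_area():
    cells = np.zeros((10, 10), dtype=np.uint8)
    cells[0:4, 0:4] = 1
    cells[7:9, 7:9] = 1
    mask = BinaryMask(cells=cells)
    objs = label_objects(mask)
    big = largest_object(objs)
    kept = isolate_object(mask, big)
    assert int(kept.cells.sum()) == big.area == 16
    assert kept.cells[8, 8] == 0

    single = BinaryMask(cells=cells[0:5, 0:5])
    (only,) = label_objects(single)
    np.testing.assert_array_equal(isolate_object(single, only).cells, single.cells)


def test_isolate_rejects_stale_object():
    cells = np.zeros((6, 6), dtype=np.uint8)
    cells[0:2, 0:2] = 1
    mask = BinaryMask(cells=cells)
    (obj,) = label_objects(mask)
    other = BinaryMask(cells=np.zeros((6, 6), dtype=np.uint8))
    with pytest.raises(ValueError):
        isolate_object(other, obj)
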
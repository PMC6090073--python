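"""Neck-boundary detection on the silhouette mask.

The cervical region sits at the narrowest part of the patient
silhouette.  A vertical virtual boundary through the silhouette's
centroid column splits the mask in two; in each half, the row with the
most background zeros is the one where the object is narrowest, and the
background-to-object transition column in that row marks the crop
boundary on that side.  The crop keeps the full image height, so no
vertical information is lost.

All indices are 0-based and crop intervals are inclusive on both ends.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .mask import BinaryMask

__all__ = ["RoiBounds", "NoNeckError", "count_max_zeros", "detect_bounds"]


class NoNeckError(RuntimeError):
    """No background/object transition found — degenerate silhouette."""


@dataclasses.dataclass(frozen=True)
class RoiBounds:
    """Inclusive crop rectangle ``(top_row, left_col)``–``(bottom_row, right_col)``.

    For neck detection the row bounds always span the full image height;
    only the columns are narrowed.
    """

    top_row: int
    bottom_row: int
    left_col: int
    right_col: int

    def __post_init__(self) -> None:
        if not 0 <= self.top_row <= self.bottom_row:
            raise ValueError(f"bad row bounds ({self.top_row}, {self.bottom_row})")
        if not 0 <= self.left_col <= self.right_col:
            raise ValueError(f"bad column bounds ({self.left_col}, {self.right_col})")

    @property
    def height(self) -> int:
        return self.bottom_row - self.top_row + 1

    @property
    def width(self) -> int:
        return self.right_col - self.left_col + 1

    def as_dict(self) -> dict[str, int]:
        return {
            "top": self.top_row,
            "bottom": self.bottom_row,
            "left": self.left_col,
            "right": self.right_col,
        }


def count_max_zeros(
    mask: BinaryMask, start_col: int, end_col: int, flag: int
) -> int:
    """Narrowest-row transition column within a column window.

    Restricted to columns ``[start_col, end_col]`` (inclusive), selects
    the row with the maximum number of zeros — the row where the object
    is narrowest — breaking ties toward the smallest row index.  That
    row is then scanned left to right within the window:

    * ``flag = 0``: return the column of the first cell whose previous
      cell is 0 and which is itself 1 (the object's left edge);
    * ``flag = 1``: return the column of the last 1-cell whose next cell
      is 0 (the object's right edge).

    Both returned columns are *object* columns, so an inclusive crop at
    these bounds never cuts into the object.

    Raises
    ------
    NoNeckError
        The selected row has no qualifying transition (e.g. the window
        is all ones, or the object runs off the window edge with no
        background beside it).
    """
    if flag not in (0, 1):
        raise ValueError(f"flag must be 0 or 1, got {flag}")
    if not 0 <= start_col <= end_col <= mask.cols - 1:
        raise ValueError(
            f"column window [{start_col}, {end_col}] outside 0..{mask.cols - 1}"
        )
    window = mask.cells[:, start_col : end_col + 1]
    zero_counts = (window == 0).sum(axis=1)
    row = int(np.argmax(zero_counts))  # argmax takes the first maximum: uppermost row
    cells = window[row]
    # Transition positions within the window.
    diffs = np.diff(cells.astype(np.int8))
    if flag == 0:
        rising = np.nonzero(diffs == 1)[0]  # cells[k] == 0, cells[k+1] == 1
        if len(rising) == 0:
            raise NoNeckError(
                f"no 0-to-1 transition in row {row}, columns {start_col}..{end_col}"
            )
        return start_col + int(rising[0]) + 1
    falling = np.nonzero(diffs == -1)[0]  # cells[k] == 1, cells[k+1] == 0
    if len(falling) == 0:
        raise NoNeckError(
            f"no 1-to-0 transition in row {row}, columns {start_col}..{end_col}"
        )
    return start_col + int(falling[-1])


def detect_bounds(mask: BinaryMask, m_c: int) -> RoiBounds:
    """Full-height crop bounds around the silhouette's narrowest span.

    ``m_c`` is the virtual boundary: the rounded centroid column of the
    silhouette.  The left half ``[0, m_c]`` yields the left crop column
    (first 0-to-1 transition in its narrowest row) and the right half
    ``[m_c, cols - 1]`` the right crop column (last 1-to-0 transition in
    its own narrowest row); the two halves may select different rows.
    Row bounds are fixed to the full image height.

    Raises
    ------
    NoNeckError
        Either half lacks a background/object transition.
    """
    if not 0 < m_c < mask.cols - 1:
        raise ValueError(f"central column {m_c} must lie strictly inside 0..{mask.cols - 1}")
    left = count_max_zeros(mask, 0, m_c, 0)
    right = count_max_zeros(mask, m_c, mask.cols - 1, 1)
    return RoiBounds(top_row=0, bottom_row=mask.rows - 1, left_col=left, right_col=right)
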
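"""Frame segmentation: global threshold, contour extraction, size filtering.

A frame is binarised with a single global threshold (FTIR-style imagery needs
no background subtraction), 8-connected foreground components are traced into
closed outer boundaries by Moore-neighbour border following, internal holes
are filled (the tracked quantity is whole-body area), and a size filter
rejects speckle noise and oversized merges outside the expected larval area
range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

# 8-neighbour directions in clockwise order, image coordinates (row, col).
_DIRS = np.array(
    [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)],
    dtype=int,
)
_DIR_INDEX = {(int(dr), int(dc)): i for i, (dr, dc) in enumerate(_DIRS)}


@dataclass
class Contour:
    """One foreground component: closed outer boundary plus filled statistics.

    Attributes
    ----------
    boundary : (B, 2) int array
        Ordered, closed pixel boundary (row, col), 0-based, first point
        8-adjacent to the last.
    area : int
        Count of filled pixels (interior + boundary, holes filled).
    centroid : (2,) float array
        Mean (row, col) of the filled pixels — the centre of mass.
    bbox : (min_row, min_col, max_row, max_col)
        Half-open bounding box of the filled pixels in frame coordinates.
    filled : 2D bool array
        Filled component mask cropped to ``bbox``.
    """

    boundary: np.ndarray
    area: int
    centroid: np.ndarray
    bbox: tuple[int, int, int, int]
    filled: np.ndarray = field(repr=False)

    def pixels(self) -> np.ndarray:
        """(P, 2) int array of filled pixel coordinates in the frame."""
        rr, cc = np.nonzero(self.filled)
        return np.column_stack((rr + self.bbox[0], cc + self.bbox[1]))

    def mask_in(self, shape: tuple[int, int]) -> np.ndarray:
        """Render the filled component into a full-frame boolean mask."""
        out = np.zeros(shape, dtype=bool)
        r0, c0, r1, c1 = self.bbox
        out[r0:r1, c0:c1] = self.filled
        return out


def binarize(frame: np.ndarray, k: int) -> np.ndarray:
    """Boolean foreground mask: pixel value strictly greater than ``k``."""
    return np.asarray(frame) > k


def _trace_boundary(mask: np.ndarray, start: tuple[int, int]) -> np.ndarray:
    """Moore-neighbour border following from ``start`` (topmost-leftmost pixel).

    ``mask`` must be padded with a 1-px background frame so neighbour lookups
    never leave the array.  Returns the closed outer boundary in clockwise
    order.  Jacob's stopping criterion: terminate on re-entering the start
    pixel from the original backtrack direction.
    """
    boundary = [start]
    # Backtrack begins at the western neighbour, background by construction
    # because the start pixel is topmost-leftmost.
    backtrack = (start[0], start[1] - 1)
    cur = start
    first_step: tuple[tuple[int, int], tuple[int, int]] | None = None
    while True:
        d0 = _DIR_INDEX[(backtrack[0] - cur[0], backtrack[1] - cur[1])]
        nxt = None
        for step in range(1, 9):
            d = (d0 + step) % 8
            cand = (cur[0] + int(_DIRS[d][0]), cur[1] + int(_DIRS[d][1]))
            if mask[cand]:
                nxt = cand
                break
            backtrack = cand
        if nxt is None:  # isolated pixel, boundary is the pixel itself
            break
        if first_step is None:
            first_step = (cur, nxt)
        elif (cur, nxt) == first_step:
            break  # about to repeat the first transition: contour closed
        boundary.append(nxt)
        cur = nxt
    if len(boundary) > 1 and boundary[-1] == boundary[0]:
        boundary.pop()
    return np.array(boundary, dtype=int)


def extract_contours(mask: np.ndarray) -> list[Contour]:
    """Outer contours of all 8-connected foreground components.

    Holes inside a component are filled before computing area and centroid.
    An empty mask yields an empty list.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    labels, n = measure.label(mask, connectivity=2, return_num=True)
    contours: list[Contour] = []
    for region in measure.regionprops(labels):
        r0, c0, r1, c1 = region.bbox
        local = labels[r0:r1, c0:c1] == region.label
        filled = ndimage.binary_fill_holes(local)
        # Pad so boundary tracing never leaves the array.
        padded = np.pad(filled, 1)
        rr, cc = np.nonzero(padded)
        start_i = np.lexsort((cc, rr))[0]  # topmost, then leftmost
        start = (int(rr[start_i]), int(cc[start_i]))
        boundary = _trace_boundary(padded, start)
        boundary = boundary - 1 + np.array([r0, c0])  # un-pad, to frame coords
        pix_r, pix_c = np.nonzero(filled)
        centroid = np.array([pix_r.mean() + r0, pix_c.mean() + c0])
        contours.append(
            Contour(
                boundary=boundary,
                area=int(filled.sum()),
                centroid=centroid,
                bbox=(r0, c0, r1, c1),
                filled=filled,
            )
        )
    return contours


def filter_contours(
    contours: list[Contour], min_area: float, max_area: float = np.inf
) -> list[Contour]:
    """Keep contours with ``min_area <= area <= max_area`` (order preserved)."""
    if min_area < 0 or min_area > max_area:
        raise ValueError(f"invalid size bounds [{min_area}, {max_area}]")
    return [c for c in contours if min_area <= c.area <= max_area]


def segment_frame(
    frame: np.ndarray, k: int, min_area: float, max_area: float = np.inf
) -> list[Contour]:
    """Threshold → contours → size filter, the per-frame front end of tracking."""
    return filter_contours(extract_contours(binarize(frame, k)), min_area, max_area)
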
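"""Per-animal shape geometry: midline (spine), landmarks, head, bending angle.

The midline is estimated from the body contour alone: random points are
deployed inside the eroded body mask, each is joined to its nearest boundary
point, and the chord midpoints — which scatter symmetrically around the true
midline — are ordered along the body axis, averaged in arc-position bins and
passed to a least-squares smoothing spline.  The spline ends are extended to
the body tips along the local tangent.  Seven landmarks at equal arc-length
fractions give the head (1), centre (3) and tail (5) positions from which
the signed bending angle phi is computed; |phi| is discretised into the four
conventional head-cast classes (none < 20 deg <= slight < 30 deg <= average
< 50 deg <= strong).

The head end is identified as the spine end nearer the largest dark blob
inside the body (the head is the biggest dark region in FTIR imagery); when
no sufficiently dark and large blob exists, orientation falls back to the
centroid movement vector and, failing that, persists from the last confident
frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import interpolate, ndimage
from scipy.spatial import cKDTree

from .segmentation import Contour


class BendClass(str, Enum):
    """Discrete head-cast intensity classes on |phi| (degrees)."""

    NONE = "none"        # |phi| < 20
    SLIGHT = "slight"    # 20 <= |phi| < 30
    AVERAGE = "average"  # 30 <= |phi| < 50
    STRONG = "strong"    # |phi| >= 50


BEND_BOUNDARIES = (20.0, 30.0, 50.0)


@dataclass
class Spine:
    """Body midline from end A to end B with seven equidistant landmarks."""

    points: np.ndarray          # (M, 2) sub-pixel polyline, (row, col)
    arc_length: float
    landmarks: np.ndarray       # (7, 2): landmark i at arc fraction i/6 from A

    def reversed(self) -> "Spine":
        return Spine(
            points=self.points[::-1].copy(),
            arc_length=self.arc_length,
            landmarks=self.landmarks[::-1].copy(),
        )


@dataclass
class LarvaFrameState:
    """Everything measured for one animal in one frame."""

    contour: Contour
    spine: Spine | None = None
    head_end: str = "?"                   # "A" | "B" | "?"
    head_detected: bool = False
    phi: float = np.nan                   # signed bending angle, degrees
    bend_class: BendClass | None = None
    collision: bool = False
    shape_suspect: bool = False
    frame: int = -1

    @property
    def area(self) -> int:
        return self.contour.area

    @property
    def centroid(self) -> np.ndarray:
        return self.contour.centroid

    def _oriented_landmarks(self) -> np.ndarray | None:
        if self.spine is None or self.head_end == "?":
            return None
        lm = self.spine.landmarks
        return lm if self.head_end == "A" else lm[::-1]

    @property
    def head(self) -> np.ndarray | None:
        lm = self._oriented_landmarks()
        return None if lm is None else lm[1]

    @property
    def mid(self) -> np.ndarray | None:
        lm = self._oriented_landmarks()
        return None if lm is None else lm[3]

    @property
    def tail(self) -> np.ndarray | None:
        lm = self._oriented_landmarks()
        return None if lm is None else lm[5]


def _polyline_arc(points: np.ndarray) -> np.ndarray:
    steps = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate(([0.0], np.cumsum(steps)))


def _interp_along(points: np.ndarray, arc: np.ndarray, s: np.ndarray) -> np.ndarray:
    r = np.interp(s, arc, points[:, 0])
    c = np.interp(s, arc, points[:, 1])
    return np.column_stack((r, c))


def place_landmarks(points: np.ndarray, n: int = 7) -> np.ndarray:
    """``n`` points at equal arc-length fractions along a midline polyline."""
    arc = _polyline_arc(points)
    if arc[-1] <= 0:
        raise ValueError("zero-length spine")
    return _interp_along(points, arc, np.linspace(0.0, arc[-1], n))


def _find_tip(
    end: np.ndarray, tangent: np.ndarray, boundary: np.ndarray
) -> np.ndarray | None:
    """Body tip beyond a spline end: the boundary point farthest along the
    outward tangent, preferring points close to the tangent line (so flat
    body ends resolve to their centre rather than a corner)."""
    norm = np.linalg.norm(tangent)
    if norm == 0:
        return None
    t = tangent / norm
    rel = boundary - end
    proj = rel @ t
    ahead = proj > 0
    if not ahead.any():
        return None
    perp = np.abs(rel[:, 0] * t[1] - rel[:, 1] * t[0])
    cand = ahead & (perp < 6.0)
    if not cand.any():
        cand = ahead
    best_proj = proj[cand].max()
    near_tip = cand & (proj >= best_proj - 1.5)
    # Tip = furthest extent along the tangent at the mean lateral offset of
    # the tip-most boundary points: centres a flat end edge without the
    # inward bias that averaging the cap arc would introduce.
    n_perp = np.array([-t[1], t[0]])
    lateral = float((rel[near_tip] @ n_perp).mean())
    return end + t * best_proj + n_perp * lateral


def estimate_spine(
    contour: Contour,
    n_points: int = 200,
    seed: int | np.random.Generator = 0,
    min_aspect: float = 1.5,
) -> Spine:
    """Midline of a body contour via random interior chord midpoints.

    Random points inside the 3x3-eroded body mask are joined to their nearest
    boundary point; the chord midpoints are ordered by projection on the
    principal axis, refined by arc position along a preliminary curve,
    averaged in bins and fitted with a least-squares smoothing spline whose
    ends are extended to the body tips.  Deterministic for a given seed.

    Raises
    ------
    ValueError
        "shape too thin" if erosion empties the mask; "degenerate shape" if
        the body is near-circular (principal-axis aspect below ``min_aspect``).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    filled = contour.filled
    origin = np.array([contour.bbox[0], contour.bbox[1]], dtype=float)

    eroded = ndimage.binary_erosion(filled, structure=np.ones((3, 3)))
    if not eroded.any():
        raise ValueError("shape too thin")

    interior = np.column_stack(np.nonzero(eroded)).astype(float) + origin
    # Aspect from principal-axis standard deviations of the filled body.
    body = np.column_stack(np.nonzero(filled)).astype(float)
    cov = np.cov((body - body.mean(axis=0)).T)
    evals = np.sort(np.linalg.eigvalsh(cov))
    if evals[0] <= 0 or np.sqrt(evals[1] / evals[0]) < min_aspect:
        raise ValueError("degenerate shape")

    idx = rng.integers(0, interior.shape[0], size=n_points)
    pts = interior[idx]
    boundary = contour.boundary.astype(float)
    btree = cKDTree(boundary)
    # Shortest transversal line through each random point: its nearest
    # boundary point b1 plus the nearest boundary point on the opposite side
    # of the point; the centre of that line samples the midline.
    k = min(len(boundary), 48)
    _, nn = btree.query(pts, k=k)
    nn = np.atleast_2d(nn)
    b1 = boundary[nn[:, 0]]
    cand = boundary[nn]                                   # (n, k, 2)
    to_cand = cand - pts[:, None, :]
    to_b1 = b1 - pts                                      # (n, 2)
    opposite = np.einsum("nkd,nd->nk", to_cand, to_b1) <= 1e-9
    opposite[:, 0] = False
    has_b2 = opposite.any(axis=1)
    first = np.argmax(opposite, axis=1)
    b2 = cand[np.arange(len(pts)), first]
    mids = np.where(has_b2[:, None], 0.5 * (b1 + b2), 0.5 * (pts + b1))
    chord_len = np.where(
        has_b2,
        np.linalg.norm(b2 - b1, axis=1),
        2.0 * np.linalg.norm(to_b1, axis=1),
    )
    # Chords near the body tips connect an end cap to a side wall and their
    # midpoints stray off the midline; keep only chords of typical width.
    med_len = np.median(chord_len)
    keep = (chord_len > 0.55 * med_len) & (chord_len < 1.8 * med_len)
    if keep.sum() >= 20:
        mids = mids[keep]

    # Order along the body: principal-axis projection, then refine by arc
    # position on a preliminary binned polyline (handles curved bodies).
    centred = mids - mids.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    order = np.argsort(centred @ vt[0])
    prelim = _binned_polyline(mids[order], n_bins=max(6, int(len(mids) / 15)))
    dense = _densify(prelim, step=1.0)
    arc = _polyline_arc(dense)
    _, pos = cKDTree(dense).query(mids)
    order = np.argsort(arc[pos])

    binned = _binned_polyline(mids[order], n_bins=max(8, int(len(mids) / 12)))
    spline_pts = _fit_spline(binned)

    # The outermost spline samples rest on sparse end bins and may hook;
    # trim them and bridge straight to the body tips instead.
    spline_pts = spline_pts[6:-6]
    head_ext = _find_tip(spline_pts[0], spline_pts[0] - spline_pts[6], boundary)
    tail_ext = _find_tip(spline_pts[-1], spline_pts[-1] - spline_pts[-7], boundary)
    parts = []
    if head_ext is not None:
        parts.append(head_ext[None, :])
    parts.append(spline_pts)
    if tail_ext is not None:
        parts.append(tail_ext[None, :])
    full = np.vstack(parts)

    # Resample evenly in arc length.
    arc = _polyline_arc(full)
    if arc[-1] <= 0:
        raise ValueError("zero-length spine")
    even = _interp_along(full, arc, np.linspace(0, arc[-1], 100))
    arc_even = _polyline_arc(even)
    landmarks = _interp_along(even, arc_even, np.linspace(0, arc_even[-1], 7))
    return Spine(points=even, arc_length=float(arc_even[-1]), landmarks=landmarks)


def _binned_polyline(ordered_mids: np.ndarray, n_bins: int) -> np.ndarray:
    """Average ordered midpoints in equal-count bins along the body."""
    groups = np.array_split(ordered_mids, n_bins)
    return np.array([g.mean(axis=0) for g in groups if len(g)])


def _densify(points: np.ndarray, step: float) -> np.ndarray:
    arc = _polyline_arc(points)
    if arc[-1] <= 0:
        return points
    n = max(int(arc[-1] / step), 2)
    return _interp_along(points, arc, np.linspace(0, arc[-1], n))


def _fit_spline(binned: np.ndarray) -> np.ndarray:
    """Smoothing spline through bin means, sampled densely."""
    if len(binned) < 4:
        return _densify(binned, step=0.5)
    arc = _polyline_arc(binned)
    u = arc / arc[-1]
    # Bin means carry residual scatter ~0.5 px; allow that much slack.
    tck, _ = interpolate.splprep(
        [binned[:, 0], binned[:, 1]], u=u, s=len(binned) * 0.25, k=3
    )
    uu = np.linspace(0, 1, 80)
    r, c = interpolate.splev(uu, tck)
    return np.column_stack((r, c))


def detect_head(
    frame: np.ndarray,
    contour: Contour,
    spine: Spine,
    dark_mad_factor: float = 2.0,
    min_blob_frac: float = 0.01,
    tie_ratio: float = 1.2,
) -> tuple[str, bool]:
    """Identify the head end as the spine end nearer the biggest dark blob.

    Interior pixels more than ``dark_mad_factor`` MADs below the body median
    (the anti-aliased rim is excluded by a 2-px erosion) are grouped into
    blobs; the largest blob above ``min_blob_frac`` of the body area marks
    the head.  Near-ties between the two largest blobs leave the head
    undetected so the motion fallback can decide.

    Returns ``(head_end, head_detected)`` with ``head_end in {"A","B","?"}``.
    """
    r0, c0, r1, c1 = contour.bbox
    local = np.asarray(frame)[r0:r1, c0:c1].astype(float)
    core = ndimage.binary_erosion(contour.filled, np.ones((3, 3)))
    if core.sum() < 4:
        return "?", False
    vals = local[core]
    med = np.median(vals)
    mad = np.median(np.abs(vals - med))
    dark = core & (local < med - dark_mad_factor * max(mad, 2.0))
    if not dark.any():
        return "?", False
    labels, n = ndimage.label(dark, structure=np.ones((3, 3)))
    sizes = ndimage.sum_labels(dark, labels, index=np.arange(1, n + 1))
    min_size = max(3.0, min_blob_frac * contour.area)
    big = np.nonzero(sizes >= min_size)[0]
    if big.size == 0:
        return "?", False
    ranked = big[np.argsort(sizes[big])[::-1]]
    if ranked.size >= 2 and sizes[ranked[0]] / sizes[ranked[1]] < tie_ratio:
        return "?", False
    blob_mask = labels == ranked[0] + 1
    rr, cc = np.nonzero(blob_mask)
    blob_centroid = np.array([rr.mean() + r0, cc.mean() + c0])
    d_a = np.linalg.norm(blob_centroid - spine.points[0])
    d_b = np.linalg.norm(blob_centroid - spine.points[-1])
    return ("A" if d_a <= d_b else "B"), True


def orient_by_motion(
    history: list[LarvaFrameState],
    current: LarvaFrameState,
    noise_floor: float = 1.0,
    window: int = 5,
) -> str:
    """Head end from the centroid movement vector, else persisted orientation.

    The head is the spine end whose outward direction has the larger positive
    dot product with the recent centroid displacement.  Sub-noise
    displacement keeps the previous confident orientation.
    """
    if current.spine is None:
        return "?"
    prev = [s for s in history if s is not None][-window:]
    move = None
    if prev:
        move = current.centroid - prev[0].centroid
        if np.linalg.norm(move) <= noise_floor:
            move = None
    if move is not None:
        lm = current.spine.landmarks
        centre = lm[3]
        da = float(np.dot(lm[0] - centre, move))
        db = float(np.dot(lm[6] - centre, move))
        if da != db:
            return "A" if da > db else "B"
    for s in reversed(prev):
        if s.head_end in ("A", "B"):
            return s.head_end
    return "?"


def bending_angle(
    head: np.ndarray, mid: np.ndarray, tail: np.ndarray
) -> tuple[float, BendClass]:
    """Signed bending angle phi (degrees) at the body centre, plus its class.

    phi is the angle between the travel axis tail->mid and the head segment
    mid->head, positive when the head deviates to the animal's left (image
    coordinates, row increasing downward).
    """
    head = np.asarray(head, float)
    mid = np.asarray(mid, float)
    tail = np.asarray(tail, float)
    u = mid - tail
    w = head - mid
    if np.allclose(u, 0) or np.allclose(w, 0):
        raise ValueError("coincident landmarks")
    # (row, col) -> (x=col, y=row); y grows downward, so negate the cross
    # product to make leftward-of-travel positive.
    cross = u[1] * w[0] - u[0] * w[1]
    dot = float(u @ w)
    phi = -np.degrees(np.arctan2(cross, dot))
    if phi <= -180.0:
        phi += 360.0
    return float(phi), classify_bend(phi)


def classify_bend(phi: float) -> BendClass:
    """Head-cast class of a bending angle by the 20/30/50-degree boundaries."""
    a = abs(phi)
    if a < BEND_BOUNDARIES[0]:
        return BendClass.NONE
    if a < BEND_BOUNDARIES[1]:
        return BendClass.SLIGHT
    if a < BEND_BOUNDARIES[2]:
        return BendClass.AVERAGE
    return BendClass.STRONG
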
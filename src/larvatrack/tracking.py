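"""Identity-preserving multi-animal tracking with two-animal collision resolution.

Frame-to-frame assignment combines centroid distance with contour overlap:
each live track picks the candidate blob with the largest pixel overlap with
its previous body (ties by centroid distance) within a gating radius of half
a body length.  When two tracks pick the same blob the contours have merged
and a collision event opens: the participants' movement vectors between
(t-2) and (t-1) translate their previous filled contours to hypothetical
positions at t, uniquely covered merged-blob pixels go to the respective
animal, and the remaining pixels are split by nearest neighbour.  If a
partition piece shrinks below half its pre-collision area, or the piece
area ratio drifts more than twofold from the pre-collision ratio, the event
is unresolved and both tracks are suspended.  Collisions with more than two
participants are never resolved.  A suspended track is revived when a blob
reappears within the gating radius of its last centroid within a fixed
number of frames; otherwise a new identity is opened.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.spatial import cKDTree

from .config import RunConfig
from .calibration import compute_histogram, otsu_threshold
from .geometry import (
    LarvaFrameState,
    bending_angle,
    classify_bend,
    detect_head,
    estimate_spine,
    orient_by_motion,
)
from .segmentation import Contour, extract_contours, segment_frame


@dataclass
class Track:
    """Identity-preserving per-animal time series of frame states."""

    id: int
    states: dict[int, LarvaFrameState] = field(default_factory=dict)

    @property
    def first_frame(self) -> int:
        return min(self.states)

    @property
    def last_frame(self) -> int:
        return max(self.states)

    def state(self, frame: int) -> LarvaFrameState | None:
        return self.states.get(frame)

    def is_complete(self, n_frames: int) -> bool:
        """Covers every frame of the movie (no gaps, spans 0..n_frames-1)."""
        return len(self.states) == n_frames and self.first_frame == 0

    def centroids(self, n_frames: int) -> np.ndarray:
        """(T, 2) centroid series with NaN at frames without a state."""
        out = np.full((n_frames, 2), np.nan)
        for f, s in self.states.items():
            if 0 <= f < n_frames:
                out[f] = s.centroid
        return out


@dataclass
class CollisionEvent:
    """A contiguous two-animal contact."""

    frame_start: int
    frame_end: int
    participants: tuple[int, ...]
    v1: np.ndarray | None = None
    v2: np.ndarray | None = None
    resolved: bool = True


@dataclass
class TrackSet:
    """All tracks and collision events of one movie."""

    tracks: list[Track]
    events: list[CollisionEvent]
    n_frames: int
    config: RunConfig

    def complete_tracks(self) -> list[Track]:
        return [t for t in self.tracks if t.is_complete(self.n_frames)]

    def by_id(self, track_id: int) -> Track:
        for t in self.tracks:
            if t.id == track_id:
                return t
        raise KeyError(track_id)


def assign_blobs(
    prev_states: dict[int, LarvaFrameState],
    contours: list[Contour],
    d_max: float,
    frame_shape: tuple[int, int],
) -> tuple[dict[int, int], dict[int, list[int]], list[int]]:
    """Match previous tracks to current-frame contours.

    Returns ``(matches, merges, unmatched)``: track-id -> contour index for
    unique matches; contour index -> list of track ids for merged blobs
    (collision candidates); and the indices of contours no track claimed.
    """
    choices: dict[int, int] = {}
    for tid, st in prev_states.items():
        best: tuple[float, float] | None = None
        best_j = None
        for j, cont in enumerate(contours):
            d = float(np.linalg.norm(cont.centroid - st.centroid))
            overlap = _overlap_area(st.contour, cont)
            if d >= d_max and overlap == 0:
                continue
            key = (-overlap, d)
            if best is None or key < best:
                best, best_j = key, j
        if best_j is not None:
            choices[tid] = best_j

    by_contour: dict[int, list[int]] = {}
    for tid, j in choices.items():
        by_contour.setdefault(j, []).append(tid)
    matches = {tids[0]: j for j, tids in by_contour.items() if len(tids) == 1}
    merges = {j: sorted(tids) for j, tids in by_contour.items() if len(tids) > 1}
    claimed = set(by_contour)
    unmatched = [j for j in range(len(contours)) if j not in claimed]
    return matches, merges, unmatched


def _overlap_area(a: Contour, b: Contour) -> int:
    ar0, ac0, ar1, ac1 = a.bbox
    br0, bc0, br1, bc1 = b.bbox
    r0, c0 = max(ar0, br0), max(ac0, bc0)
    r1, c1 = min(ar1, br1), min(ac1, bc1)
    if r1 <= r0 or c1 <= c0:
        return 0
    av = a.filled[r0 - ar0 : r1 - ar0, c0 - ac0 : c1 - ac0]
    bv = b.filled[r0 - br0 : r1 - br0, c0 - bc0 : c1 - bc0]
    return int((av & bv).sum())


def resolve_collision(
    merged: Contour,
    prev1: LarvaFrameState,
    prev2: LarvaFrameState,
    v1: np.ndarray,
    v2: np.ndarray,
    frame_shape: tuple[int, int],
) -> tuple[Contour, Contour] | None:
    """Partition a merged two-animal blob back into per-animal contours.

    The previous filled contours are translated rigidly by the pre-collision
    movement vectors; uniquely covered pixels of the merged blob belong to
    the covering animal, all remaining pixels go to the nearest claimed
    pixel.  Returns ``None`` when the partition fails the quality criterion.
    """
    H, W = frame_shape
    merged_pix = merged.pixels()
    merged_idx = merged_pix[:, 0] * W + merged_pix[:, 1]

    def hyp_index(prev: LarvaFrameState, v: np.ndarray) -> np.ndarray:
        pix = prev.contour.pixels() + np.rint(v).astype(int)
        ok = (
            (pix[:, 0] >= 0) & (pix[:, 0] < H) & (pix[:, 1] >= 0) & (pix[:, 1] < W)
        )
        pix = pix[ok]
        return pix[:, 0] * W + pix[:, 1]

    h1 = hyp_index(prev1, v1)
    h2 = hyp_index(prev2, v2)
    in1 = np.isin(merged_idx, np.setdiff1d(h1, h2, assume_unique=False))
    in2 = np.isin(merged_idx, np.setdiff1d(h2, h1, assume_unique=False))
    if not in1.any() or not in2.any():
        return None
    rest = ~(in1 | in2)
    if rest.any():
        t1 = cKDTree(merged_pix[in1])
        t2 = cKDTree(merged_pix[in2])
        d1, _ = t1.query(merged_pix[rest])
        d2, _ = t2.query(merged_pix[rest])
        to1 = d1 <= d2
        idx_rest = np.nonzero(rest)[0]
        in1[idx_rest[to1]] = True
        in2[idx_rest[~to1]] = True

    pieces = []
    for sel in (in1, in2):
        pix = merged_pix[sel]
        r0, c0 = pix.min(axis=0)
        r1, c1 = pix.max(axis=0) + 1
        local = np.zeros((r1 - r0, c1 - c0), dtype=bool)
        local[pix[:, 0] - r0, pix[:, 1] - c0] = True
        sub = extract_contours(local)
        if not sub:
            return None
        largest = max(sub, key=lambda c: c.area)
        sr0, sc0, sr1, sc1 = largest.bbox
        piece = Contour(
            boundary=largest.boundary + np.array([r0, c0]),
            area=largest.area,
            centroid=largest.centroid + np.array([r0, c0]),
            bbox=(sr0 + r0, sc0 + c0, sr1 + r0, sc1 + c0),
            filled=largest.filled,
        )
        pieces.append(piece)

    a1, a2 = prev1.contour.area, prev2.contour.area
    p1, p2 = pieces[0].area, pieces[1].area
    if p1 < 0.5 * a1 or p2 < 0.5 * a2:
        return None
    ratio_prev = a1 / a2
    ratio_now = p1 / p2
    drift = ratio_now / ratio_prev
    if drift > 2.0 or drift < 0.5:
        return None
    return pieces[0], pieces[1]


class _Tracker:
    """Stateful frame-by-frame tracker (driven by :func:`track_movie`)."""

    def __init__(self, config: RunConfig, frame_shape: tuple[int, int]):
        self.cfg = config
        self.shape = frame_shape
        self.tracks: list[Track] = []
        self.events: list[CollisionEvent] = []
        self._open_events: dict[tuple[int, int], CollisionEvent] = {}
        self._next_id = 0
        self._suspended: dict[int, int] = {}  # track id -> last frame seen
        # Unresolved collisions: participant set -> pre-collision contours.
        self._pending: dict[frozenset[int], list[Contour]] = {}
        self._event_snapshots: dict[tuple[int, ...], list[Contour]] = {}

    def _new_track(self, frame: int, state: LarvaFrameState) -> Track:
        tr = Track(id=self._next_id)
        self._next_id += 1
        tr.states[frame] = state
        self.tracks.append(tr)
        return tr

    def _live_states(self, t: int) -> dict[int, LarvaFrameState]:
        out = {}
        for tr in self.tracks:
            st = tr.state(t - 1)
            if st is not None:
                out[tr.id] = st
        return out

    def step(self, t: int, frame: np.ndarray, contours: list[Contour]) -> None:
        cfg = self.cfg
        prev = self._live_states(t)
        matches, merges, unmatched = assign_blobs(
            prev, contours, cfg.d_max, self.shape
        )

        taken_pairs: list[tuple[int, Contour, bool]] = []  # (tid, contour, collision)
        for tid, j in matches.items():
            taken_pairs.append((tid, contours[j], False))

        for j, tids in merges.items():
            resolved_pair = None
            ev_key = tuple(sorted(tids))
            if len(tids) == 2:
                tr1, tr2 = (self.by_id(tid) for tid in tids)
                s1p, s2p = tr1.state(t - 1), tr2.state(t - 1)
                s1pp, s2pp = tr1.state(t - 2), tr2.state(t - 2)
                if None not in (s1p, s2p, s1pp, s2pp):
                    v1 = s1p.centroid - s1pp.centroid
                    v2 = s2p.centroid - s2pp.centroid
                    resolved_pair = resolve_collision(
                        contours[j], s1p, s2p, v1, v2, self.shape
                    )
                else:
                    v1 = v2 = np.zeros(2)
            else:
                v1 = v2 = None
            ev = self._open_events.get(ev_key)
            if ev is None or ev.frame_end < t - 1:
                ev = CollisionEvent(
                    frame_start=t,
                    frame_end=t,
                    participants=ev_key,
                    v1=v1,
                    v2=v2,
                    resolved=resolved_pair is not None,
                )
                self.events.append(ev)
                self._open_events[ev_key] = ev
                snap = []
                for tid in ev_key:
                    st = self.by_id(tid).state(t - 1)
                    if st is not None:
                        snap.append(st.contour)
                self._event_snapshots[ev_key] = snap
            else:
                ev.frame_end = t
                ev.resolved = ev.resolved and resolved_pair is not None
            if resolved_pair is not None:
                for tid, piece in zip(ev_key, resolved_pair):
                    taken_pairs.append((tid, piece, True))
            else:
                ev.resolved = False
                for tid in tids:
                    self._suspended[tid] = t - 1
                self._pending[frozenset(tids)] = self._event_snapshots.get(
                    ev_key, []
                )

        # Tracks that claimed nothing this frame become suspended.
        for tid in prev:
            if tid not in {p[0] for p in taken_pairs} and tid not in self._suspended:
                self._suspended[tid] = t - 1

        # Unclaimed blobs: revive a recently suspended track or open a new one.
        for j in unmatched:
            cont = contours[j]
            best_tid, best_d = None, np.inf
            for tid, last in self._suspended.items():
                if t - last > cfg.suspend_max:
                    continue
                st = self.by_id(tid).state(last)
                # Area consistency keeps a still-merged collision blob from
                # being adopted as a single animal.
                if not 0.5 * st.area <= cont.area <= 1.5 * st.area:
                    continue
                d = float(np.linalg.norm(cont.centroid - st.centroid))
                if d < cfg.d_max and d < best_d:
                    best_tid, best_d = tid, d
            if best_tid is not None and self._still_merged(cont):
                best_tid = None  # blob is the unseparated collision blob
            if best_tid is not None:
                del self._suspended[best_tid]
                self._pending = {
                    p: c for p, c in self._pending.items() if best_tid not in p
                }
                taken_pairs.append((best_tid, cont, False))
            else:
                state = self._make_state(t, frame, cont, None, collision=False)
                self._new_track(t, state)

        for tid, cont, coll in taken_pairs:
            tr = self.by_id(tid)
            self._suspended.pop(tid, None)
            state = self._make_state(t, frame, cont, tr, collision=coll)
            tr.states[t] = state

        # Retire long-suspended tracks and stale collision snapshots.
        self._suspended = {
            tid: last
            for tid, last in self._suspended.items()
            if t - last <= cfg.suspend_max
        }
        self._pending = {
            p: c for p, c in self._pending.items() if p <= set(self._suspended)
        }

    def _still_merged(self, cont: Contour) -> bool:
        """True when ``cont`` still covers the pre-collision bodies of every
        participant of some unresolved collision (the blob has not split)."""
        for pair, snaps in self._pending.items():
            if not snaps or not pair <= set(self._suspended):
                continue
            if all(
                _overlap_area(s, cont) > 0.25 * s.area for s in snaps
            ):
                return True
        return False

    def by_id(self, tid: int) -> Track:
        for tr in self.tracks:
            if tr.id == tid:
                return tr
        raise KeyError(tid)

    def _make_state(
        self,
        t: int,
        frame: np.ndarray,
        contour: Contour,
        track: Track | None,
        collision: bool,
    ) -> LarvaFrameState:
        state = LarvaFrameState(contour=contour, collision=collision, frame=t)
        seed = np.random.SeedSequence(
            [self.cfg.seed & 0x7FFFFFFF, t, int(contour.centroid[0]) & 0xFFFF]
        )
        try:
            state.spine = estimate_spine(
                contour,
                n_points=self.cfg.spine_points,
                seed=np.random.default_rng(seed),
            )
        except ValueError:
            state.shape_suspect = True
            return self._orient(state, track)
        tips = state.spine.points
        if (
            np.linalg.norm(tips[0] - tips[-1]) < 0.25 * state.spine.arc_length
        ):
            state.shape_suspect = True
        head_end, detected = detect_head(frame, contour, state.spine)
        state.head_end, state.head_detected = head_end, detected
        state = self._orient(state, track)
        if state.head_end in ("A", "B"):
            try:
                state.phi, state.bend_class = bending_angle(
                    state.head, state.mid, state.tail
                )
            except ValueError:
                pass
        return state

    def _orient(self, state: LarvaFrameState, track: Track | None) -> LarvaFrameState:
        if state.head_detected or state.spine is None:
            return state
        history = []
        if track is not None:
            frames = sorted(track.states)
            history = [track.states[f] for f in frames[-6:]]
        state.head_end = orient_by_motion(history, state)
        return state


def track_movie(
    frames: Iterable[np.ndarray] | np.ndarray, config: RunConfig | None = None
) -> TrackSet:
    """Track a movie: per frame threshold -> contours -> size filter ->
    geometry -> assignment -> collision handling.

    With ``config.threshold=None`` the Otsu threshold of the first frame is
    used for the whole movie (self-calibration on the bimodal histogram).
    Deterministic for a given config.
    """
    cfg = config or RunConfig()
    frames = iter(frames) if not isinstance(frames, np.ndarray) else iter(frames)
    try:
        first = next(frames)
    except StopIteration:
        raise ValueError("empty movie") from None

    threshold = cfg.threshold
    if threshold is None:
        threshold = otsu_threshold(compute_histogram(first)).k
    tracker = _Tracker(cfg, first.shape)

    n_frames = 0
    for t, frame in enumerate(_chain_first(first, frames)):
        if frame.shape != first.shape:
            raise ValueError(f"frame {t}: shape {frame.shape} != {first.shape}")
        contours = segment_frame(frame, threshold, cfg.min_area, cfg.max_area)
        tracker.step(t, frame, contours)
        n_frames = t + 1

    return TrackSet(
        tracks=tracker.tracks,
        events=tracker.events,
        n_frames=n_frames,
        config=cfg,
    )


def _chain_first(first: np.ndarray, rest: Iterable[np.ndarray]):
    yield first
    yield from rest
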
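"""Comparison of tracking output against synthetic-scene ground truth."""

from __future__ import annotations

import numpy as np

from .synthetic import GroundTruth
from .tracking import TrackSet


def match_tracks(track_set: TrackSet, truth: GroundTruth) -> dict[int, int]:
    """Map each track id to the ground-truth animal nearest at its first frame."""
    mapping: dict[int, int] = {}
    for tr in track_set.tracks:
        f = tr.first_frame
        c = tr.states[f].centroid
        d = np.linalg.norm(truth.centroids[f] - c, axis=1)
        mapping[tr.id] = int(np.argmin(d))
    return mapping


def count_identity_swaps(
    track_set: TrackSet, truth: GroundTruth, gate: float | None = None
) -> int:
    """Frames where a track's centroid is nearest a different animal than
    the one it started on."""
    mapping = match_tracks(track_set, truth)
    swaps = 0
    for tr in track_set.tracks:
        want = mapping[tr.id]
        for f, s in tr.states.items():
            d = np.linalg.norm(truth.centroids[f] - s.centroid, axis=1)
            if gate is not None and d.min() > gate:
                continue
            if int(np.argmin(d)) != want:
                swaps += 1
    return swaps


def identity_preserved(track_set: TrackSet, truth: GroundTruth) -> float:
    """Fraction of animals followed by a single track from the first to the
    last frame that still sits nearest its own animal at the end."""
    T = track_set.n_frames
    ok = 0
    n = truth.centroids.shape[1]
    for tr in track_set.tracks:
        if tr.first_frame != 0 or tr.last_frame != T - 1:
            continue
        d0 = np.linalg.norm(
            truth.centroids[0] - tr.states[0].centroid, axis=1
        )
        d1 = np.linalg.norm(
            truth.centroids[T - 1] - tr.states[T - 1].centroid, axis=1
        )
        if int(np.argmin(d0)) == int(np.argmin(d1)):
            ok += 1
    return ok / n


def head_orientation_accuracy(track_set: TrackSet, truth: GroundTruth) -> float:
    """Fraction of oriented frames whose head landmark is nearer the true
    head than the true tail."""
    mapping = match_tracks(track_set, truth)
    ok = tot = 0
    for tr in track_set.tracks:
        gi = mapping[tr.id]
        for f, s in tr.states.items():
            head = s.head
            if head is None:
                continue
            tot += 1
            d_head = np.linalg.norm(head - truth.landmarks[f, gi, 1])
            d_tail = np.linalg.norm(head - truth.landmarks[f, gi, 5])
            ok += d_head < d_tail
    return ok / tot if tot else 0.0


def midline_error(track_set: TrackSet, truth: GroundTruth) -> float:
    """Mean distance (px) from estimated spine points to the true midline."""
    from scipy.spatial import cKDTree

    mapping = match_tracks(track_set, truth)
    errs = []
    for tr in track_set.tracks:
        gi = mapping[tr.id]
        for f, s in tr.states.items():
            if s.spine is None:
                continue
            tree = cKDTree(truth.midlines[f, gi])
            d, _ = tree.query(s.spine.points)
            errs.append(d.mean())
    return float(np.mean(errs)) if errs else np.nan
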
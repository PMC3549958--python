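"""Assignment, collision resolution and whole-movie tracking."""

import numpy as np
import pytest

from larvatrack import (
    RunConfig,
    collision_scenario,
    render_scene,
    track_movie,
)
from larvatrack.evaluate import (
    count_identity_swaps,
    identity_preserved,
    match_tracks,
)
from larvatrack.geometry import LarvaFrameState
from larvatrack.segmentation import extract_contours
from larvatrack.tracking import assign_blobs, resolve_collision


def bar_mask(shape, r, c, h=6, w=24):
    m = np.zeros(shape, dtype=bool)
    m[r : r + h, c : c + w] = True
    return m


def state_from_mask(mask, frame=0):
    (cont,) = extract_contours(mask)
    return LarvaFrameState(contour=cont, frame=frame)


class TestAssignBlobs:
    def test_nearby_blobs_identity_mapping(self):
        shape = (60, 80)
        prev = {
            1: state_from_mask(bar_mask(shape, 10, 10)),
            2: state_from_mask(bar_mask(shape, 40, 40)),
        }
        conts = extract_contours(
            bar_mask(shape, 10, 12) | bar_mask(shape, 40, 42)
        )
        matches, merges, unmatched = assign_blobs(prev, conts, 20.0, shape)
        assert merges == {} and unmatched == []
        by_row = {tid: conts[j].centroid[0] for tid, j in matches.items()}
        assert by_row[1] < by_row[2]

    def test_merged_blob_triggers_collision(self):
        shape = (60, 80)
        prev = {
            1: state_from_mask(bar_mask(shape, 10, 10)),
            2: state_from_mask(bar_mask(shape, 17, 10)),
        }
        merged = extract_contours(bar_mask(shape, 10, 10, h=13))
        matches, merges, _ = assign_blobs(prev, merged, 20.0, shape)
        assert matches == {}
        assert list(merges.values()) == [[1, 2]]

    def test_far_blob_opens_new_track(self):
        shape = (60, 80)
        prev = {1: state_from_mask(bar_mask(shape, 5, 5))}
        conts = extract_contours(bar_mask(shape, 50, 50))
        matches, merges, unmatched = assign_blobs(prev, conts, 15.0, shape)
        assert matches == {} and unmatched == [0]


class TestResolveCollision:
    def _two_bar_setup(self, gap):
        shape = (60, 80)
        s1 = state_from_mask(bar_mask(shape, 20, 10))
        s2 = state_from_mask(bar_mask(shape, 20 + 6 + gap, 10))
        merged_mask = bar_mask(shape, 20, 10) | bar_mask(shape, 20 + 6 + gap, 10)
        (merged,) = extract_contours(merged_mask)
        return shape, s1, s2, merged

    def test_translated_bodies_partitioned(self):
        shape, s1, s2, merged = self._two_bar_setup(gap=0)
        out = resolve_collision(
            merged, s1, s2, np.array([0.0, 1.0]), np.array([0.0, -1.0]), shape
        )
        assert out is not None
        c1, c2 = out
        assert c1.area + c2.area == merged.area
        assert c1.centroid[0] < c2.centroid[0]

    def test_vanishing_piece_fails(self):
        shape, s1, s2, merged = self._two_bar_setup(gap=0)
        # both hypotheses on top of each other: no uniquely covered pixels
        out = resolve_collision(
            merged, s1, s1, np.zeros(2), np.zeros(2), shape
        )
        assert out is None


class TestTrackMovie:
    def test_single_larva_complete_track(self, single_larva_tracked):
        ts, gt = single_larva_tracked
        assert len(ts.tracks) == 1
        (tr,) = ts.tracks
        assert tr.is_complete(ts.n_frames)
        cen = tr.centroids(ts.n_frames)
        err = np.linalg.norm(cen - gt.centroids[:, 0], axis=1)
        assert np.nanmax(err) <= 1.0

    def test_five_larvae_no_swaps(self, five_larvae_tracked):
        ts, gt = five_larvae_tracked
        assert len(ts.complete_tracks()) == 5
        assert count_identity_swaps(ts, gt) == 0
        assert ts.events == []

    def test_empty_arena_empty_trackset(self):
        frames = np.full((5, 64, 64), 20, dtype=np.uint8)
        frames[:, 0, 0] = 90  # two occupied grey levels for self-calibration
        ts = track_movie(frames, RunConfig())
        assert ts.tracks == []

    def test_no_shared_contours_outside_collisions(self, five_larvae_tracked):
        ts, _ = five_larvae_tracked
        for f in range(ts.n_frames):
            seen = []
            for tr in ts.tracks:
                s = tr.state(f)
                if s is None or s.collision:
                    continue
                seen.append(tuple(np.rint(s.centroid).astype(int)))
            assert len(seen) == len(set(seen))


class TestCollisionScenes:
    def test_slight_touch_preserves_identities(self):
        spec = collision_scenario(0.3, 5, seed=2)
        frames, gt = render_scene(spec)
        ts = track_movie(frames, RunConfig(seed=1))
        assert identity_preserved(ts, gt) == 1.0
        assert len(ts.complete_tracks()) == 2
        assert any(ev.resolved for ev in ts.events)

    def test_collision_flags_cover_contact(self):
        spec = collision_scenario(0.5, 8, seed=2)
        frames, gt = render_scene(spec)
        ts = track_movie(frames, RunConfig(seed=1))
        ev = ts.events[0]
        for tid in ev.participants:
            tr = ts.by_id(tid)
            flagged = {f for f, s in tr.states.items() if s.collision}
            assert flagged  # resolution produced flagged frames
            assert flagged <= set(range(ev.frame_start, ev.frame_end + 1))

    def test_crawl_over_unresolved_and_disrupted(self):
        spec = collision_scenario(1.0, 30, seed=2)
        frames, gt = render_scene(spec)
        ts = track_movie(frames, RunConfig(seed=1))
        assert any(not ev.resolved for ev in ts.events)
        # at least one participant track is disrupted (suspended early)
        ev = next(ev for ev in ts.events if not ev.resolved)
        disrupted = [
            ts.by_id(tid).last_frame < ts.n_frames - 1 for tid in ev.participants
        ]
        assert any(disrupted)

    def test_three_animal_pileup_unresolved(self):
        shape = (90, 120)
        frames = []
        rows = [20, 40, 60]
        # three bars converge onto the middle row and merge
        for t in range(6):
            f = np.full(shape, 20, dtype=np.uint8)
            shift = min(t * 4, 16)
            for r0 in rows:
                r = r0 + (40 - r0) * shift // 20
                f[r : r + 6, 30:70] = 180
            frames.append(f)
        ts = track_movie(
            np.stack(frames),
            RunConfig(threshold=100, min_area=50, max_area=np.inf, d_max=30),
        )
        pileups = [ev for ev in ts.events if len(ev.participants) >= 3]
        assert pileups
        assert all(not ev.resolved for ev in pileups)
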
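"""Kinematics, contraction metrics, bending rate, stop/go segmentation."""

import numpy as np
import pytest

from larvatrack import (
    LarvaSpec,
    RunConfig,
    SceneSpec,
    StopGoParams,
    render_scene,
    track_movie,
)
from larvatrack.features import (
    _erase_short_runs,
    bending_rate,
    contraction_metrics,
    kinematics,
    stop_go_segmentation,
)
from larvatrack.geometry import LarvaFrameState
from larvatrack.segmentation import extract_contours
from larvatrack.tracking import Track, TrackSet


def synthetic_track(positions: np.ndarray) -> tuple[Track, int]:
    """A track whose per-frame centroids follow ``positions``."""
    tr = Track(id=0)
    m = np.zeros((5, 5), dtype=bool)
    m[1:4, 1:4] = True
    (cont,) = extract_contours(m)
    for f, pos in enumerate(positions):
        if np.any(np.isnan(pos)):
            continue
        c = extract_contours(m)[0]
        c.centroid = np.asarray(pos, dtype=float)
        tr.states[f] = LarvaFrameState(contour=c, frame=f)
    return tr, len(positions)


class TestKinematics:
    def test_straight_path_accumulates(self):
        pos = np.column_stack([np.zeros(100), np.arange(100.0)])
        tr, T = synthetic_track(pos)
        kin = kinematics(tr, T, fps=10, landmark="centroid")
        assert np.nansum(kin.step) == pytest.approx(99.0)
        assert kin.accumulated[-1] == pytest.approx(99.0)
        assert kin.dist_to_origin[-1] == pytest.approx(99.0)

    def test_closed_square_returns_to_origin(self):
        side = 10
        path = (
            [(0, i) for i in range(side)]
            + [(i, side) for i in range(side)]
            + [(side, side - i) for i in range(side)]
            + [(side - i, 0) for i in range(side + 1)]
        )
        tr, T = synthetic_track(np.array(path, dtype=float))
        kin = kinematics(tr, T, fps=10, landmark="centroid")
        assert kin.dist_to_origin[-1] == pytest.approx(0.0)
        assert kin.accumulated[-1] == pytest.approx(
            sum(
                np.linalg.norm(np.subtract(path[i + 1], path[i]))
                for i in range(len(path) - 1)
            )
        )

    def test_unit_conversion(self):
        pos = np.column_stack([np.zeros(20), 3.0 * np.arange(20)])
        tr, T = synthetic_track(pos)
        kin = kinematics(tr, T, fps=10, mm_per_px=0.1, landmark="centroid")
        assert np.nanmedian(kin.velocity) == pytest.approx(3.0)  # mm/s
        assert kin.unit == "mm"

    def test_gap_not_bridged(self):
        pos = np.column_stack([np.zeros(20), np.arange(20.0)])
        pos[8:12] = np.nan
        tr, T = synthetic_track(pos)
        kin = kinematics(tr, T, fps=10, landmark="centroid")
        # steps across the gap are undefined; accumulated skips them
        assert np.isnan(kin.step[8:13]).all()
        assert kin.accumulated[-1] == pytest.approx(7 + 7)

    def test_chunked_accumulation_associative(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(0, 50, size=(60, 2))
        tr, T = synthetic_track(pos)
        kin = kinematics(tr, T, fps=10, landmark="centroid")
        per_gap = [
            np.linalg.norm(pos[i + 1] - pos[i]) for i in range(len(pos) - 1)
        ]
        assert kin.accumulated[-1] == pytest.approx(np.sum(per_gap))


class TestContractionMetrics:
    def test_analytic_sine_period_and_intensity(self):
        t = np.arange(600)
        area = 260 + 10 * np.sin(2 * np.pi * t / 7)
        m = contraction_metrics(area, fps=10, reference_area=250)
        assert m.period_s == pytest.approx(0.70, abs=0.02)
        assert m.intensity == pytest.approx(20 / 250, rel=0.05)

    def test_constant_series(self):
        m = contraction_metrics(np.full(100, 260.0), fps=10, reference_area=260)
        assert not m.period_defined
        assert m.intensity == 0.0

    def test_random_programmed_series_recovered(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            period = rng.integers(5, 11)
            amp = rng.uniform(8, 20)
            base = rng.uniform(200, 320)
            t = np.arange(400)
            area = base + amp * np.sin(2 * np.pi * t / period)
            m = contraction_metrics(area, fps=10, reference_area=base)
            assert abs(m.period_s * 10 - period) <= 1.0
            # oracle: per-cycle excursion from known-period windows of the
            # sampled series (integer sampling clips the crest)
            cycles = [
                area[i : i + period] for i in range(0, 400 - period, period)
            ]
            oracle = np.mean([c.max() - c.min() for c in cycles]) / base
            assert m.intensity == pytest.approx(oracle, rel=0.05)

    def test_rendered_movie_period_recovered(self, single_larva_tracked):
        ts, gt = single_larva_tracked
        (tr,) = ts.tracks
        area = np.array([tr.states[f].area for f in range(ts.n_frames)], float)
        m = contraction_metrics(area, fps=10)
        assert m.period_defined
        assert m.period_s == pytest.approx(0.7, abs=0.1)


class TestBendingRate:
    def test_zero_series_no_events(self):
        df = bending_rate(np.zeros(200))
        assert df.loc[40, ["left", "right"]].sum() == 0

    def test_signed_events_counted(self):
        phi = np.zeros(60)
        phi[10:21] = 45.0
        phi[40:46] = -50.0
        df = bending_rate(phi, threshold=40)
        assert df.loc[40, "left"] == 1
        assert df.loc[40, "right"] == 1

    def test_counts_monotone_in_threshold(self):
        rng = np.random.default_rng(2)
        phi = rng.normal(0, 35, size=1000)
        df = bending_rate(phi)
        totals = (df["left"] + df["right"]).to_numpy()
        assert np.all(np.diff(totals) <= 0)


class TestStopGo:
    def _tracked_scene(self, seed=21):
        go = ((0, 60), (95, 160), (200, 260))
        larva = LarvaSpec(
            body_length=40.0,
            speed=2.0,
            go_intervals=go,
            bend_schedule=(),
        )
        spec = SceneSpec(
            larvae=(larva,), n_frames=260, arena=(360, 360), seed=seed
        )
        frames, gt = render_scene(spec)
        ts = track_movie(frames, RunConfig(seed=5))
        return ts, gt

    def test_moving_straight_is_go(self):
        ts, gt = self._tracked_scene()
        sg = stop_go_segmentation(ts)
        go_truth = gt.go[:, 0]
        # well inside programmed go runs the tracker must say go
        interior = np.zeros_like(go_truth)
        for a, b in ((0, 60), (95, 160), (200, 260)):
            interior[a + 20 : b - 3] = True
        assert sg.go[interior, 0].all()

    def test_no_false_positive_go_phases(self):
        ts, gt = self._tracked_scene()
        sg = stop_go_segmentation(ts)
        go = sg.go[:, 0]
        truth = gt.go[:, 0]
        # every detected go phase must overlap a programmed go phase
        t = 0
        while t < len(go):
            if go[t]:
                start = t
                while t < len(go) and go[t]:
                    t += 1
                assert truth[start:t].any()
            else:
                t += 1

    def test_stop_is_not_go(self):
        ts, _ = self._tracked_scene()
        sg = stop_go_segmentation(ts)
        assert np.array_equal(sg.stop, ~sg.go)

    def test_go_runs_at_least_t_go(self):
        ts, _ = self._tracked_scene()
        sg = stop_go_segmentation(ts)
        go = sg.go[:, 0].astype(int)
        edges = np.diff(np.concatenate(([0], go, [0])))
        starts = np.nonzero(edges == 1)[0]
        ends = np.nonzero(edges == -1)[0]
        assert np.all(ends - starts >= 7)

    def test_stationary_track_all_stop(self):
        larva = LarvaSpec(body_length=40.0, go_intervals=())
        spec = SceneSpec(larvae=(larva,), n_frames=80, arena=(200, 200), seed=4)
        frames, _ = render_scene(spec)
        ts = track_movie(frames, RunConfig(seed=1))
        sg = stop_go_segmentation(ts)
        assert not sg.go.any()

    def test_short_burst_erased(self):
        run = np.zeros(30, dtype=bool)
        run[10:16] = True  # 6 frames < t_go = 7
        assert not _erase_short_runs(run, 7).any()
        run[10:17] = True  # exactly 7 survives
        assert _erase_short_runs(run, 7).sum() == 7

    def test_fast_but_bent_is_stop(self):
        # speed above threshold but |phi| above beta -> head cast, not a run
        tr = Track(id=0)
        m = np.zeros((5, 5), dtype=bool)
        m[1:4, 1:4] = True
        for f in range(60):
            c = extract_contours(m)[0]
            c.centroid = np.array([10.0, 10.0 + 2 * f])
            s = LarvaFrameState(contour=c, frame=f)
            s.phi = 45.0
            tr.states[f] = s
        ts = TrackSet(
            tracks=[tr], events=[], n_frames=60, config=RunConfig()
        )
        sg = stop_go_segmentation(ts, StopGoParams())
        assert not sg.go.any()
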
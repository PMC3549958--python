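"""Time-variant behavioural features per track.

Kinematics (distance, accumulated distance, distance to origin, velocity,
acceleration) for the head, mid and tail landmarks; peristaltic contraction
period and intensity from the body-area series; bending-event counts per
side over a range of angle thresholds; and stop/go bout segmentation.

Stop/go follows the windowed-speed scheme: at full frame rate per-frame
noise and true displacement are of similar size, so speed is re-estimated
over ``t_window`` frames.  A frame is a go frame when that windowed
displacement exceeds ``v`` pixels and the bending angle magnitude stays
below ``beta`` degrees; go runs shorter than ``t_go`` frames are erased,
and the stop matrix is the logical not of the go matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .config import StopGoParams
from .tracking import Track, TrackSet


@dataclass
class KinematicSeries:
    """Per-landmark kinematics for one track (index = frame)."""

    landmark: str
    step: np.ndarray            # px per frame; NaN at gaps
    accumulated: np.ndarray     # running sum, gaps not bridged
    dist_to_origin: np.ndarray  # px from first tracked position
    velocity: np.ndarray        # px/s (or mm/s when scaled)
    acceleration: np.ndarray    # first difference of velocity x fps
    unit: str                   # "px" or "mm"


@dataclass
class ContractionMetrics:
    """Peristaltic cycle statistics of a body-area series."""

    period_s: float             # mean seconds per contraction cycle (NaN if <2 cycles)
    intensity: float            # mean per-cycle (max - min) / reference_area
    reference_area: float
    n_cycles: int
    period_defined: bool


@dataclass
class StopGoMatrix:
    """Binary T x N go/stop indicator matrices (stop = NOT go)."""

    go: np.ndarray
    stop: np.ndarray
    track_ids: list[int]


def _positions(track: Track, n_frames: int, landmark: str) -> np.ndarray:
    out = np.full((n_frames, 2), np.nan)
    for f, s in track.states.items():
        if landmark == "centroid":
            out[f] = s.centroid
        else:
            p = getattr(s, landmark)
            if p is not None:
                out[f] = p
    return out


def kinematics(
    track: Track,
    n_frames: int,
    fps: float,
    mm_per_px: float | None = None,
    landmark: str = "mid",
) -> KinematicSeries:
    """Step/accumulated/origin distances, velocity and acceleration.

    Steps are Euclidean distances between consecutive-frame positions;
    frames inside suspensions stay NaN and accumulated distance does not
    bridge the gap.  Velocity is step x fps (x mm_per_px when given).
    """
    pos = _positions(track, n_frames, landmark)
    if np.isfinite(pos[:, 0]).sum() < 2:
        raise ValueError("track too short for kinematics")
    step = np.full(n_frames, np.nan)
    d = np.linalg.norm(pos[1:] - pos[:-1], axis=1)
    step[1:] = d  # NaN propagates across gaps
    scale = mm_per_px if mm_per_px is not None else 1.0
    accumulated = np.nancumsum(step)
    accumulated[np.isnan(pos[:, 0])] = np.nan
    first = np.nonzero(np.isfinite(pos[:, 0]))[0][0]
    dist_origin = np.linalg.norm(pos - pos[first], axis=1)
    velocity = step * fps * scale
    acceleration = np.full(n_frames, np.nan)
    acceleration[1:] = np.diff(velocity) * fps
    return KinematicSeries(
        landmark=landmark,
        step=step,
        accumulated=accumulated,
        dist_to_origin=dist_origin * scale,
        velocity=velocity,
        acceleration=acceleration,
        unit="mm" if mm_per_px is not None else "px",
    )


def contraction_metrics(
    area: np.ndarray,
    fps: float,
    reference_area: float | None = None,
    smooth: int = 3,
    prominence_mad: float = 0.25,
) -> ContractionMetrics:
    """Contraction period and intensity from a body-area time series.

    Peaks are located on a lightly smoothed copy (moving mean over
    ``smooth`` frames) with prominence at least ``prominence_mad`` times the
    series MAD; the period is the mean peak-to-peak interval over fps.  Per
    cycle, the intensity is the raw-series (max - min) normalised by
    ``reference_area`` (defaults to the series median, standing in for the
    relaxed-animal reference area).
    """
    area = np.asarray(area, dtype=float)
    area = area[np.isfinite(area)]
    if area.size < 3:
        raise ValueError("area series too short")
    if reference_area is None:
        reference_area = float(np.median(area))
    med = np.median(area)
    mad = np.median(np.abs(area - med))
    if mad == 0:  # constant series: period undefined, no contraction
        return ContractionMetrics(
            period_s=np.nan,
            intensity=0.0,
            reference_area=reference_area,
            n_cycles=0,
            period_defined=False,
        )
    kernel = np.ones(smooth) / smooth
    smoothed = np.convolve(area, kernel, mode="same")
    peaks, _ = find_peaks(smoothed, prominence=prominence_mad * mad)
    if peaks.size < 3:
        return ContractionMetrics(
            period_s=np.nan,
            intensity=0.0,
            reference_area=reference_area,
            n_cycles=max(peaks.size - 1, 0),
            period_defined=False,
        )
    intervals = np.diff(peaks)
    period_s = float(intervals.mean() / fps)
    excursions = [
        float(area[a : b + 1].max() - area[a : b + 1].min())
        for a, b in zip(peaks[:-1], peaks[1:])
    ]
    intensity = float(np.mean(excursions) / reference_area)
    return ContractionMetrics(
        period_s=period_s,
        intensity=intensity,
        reference_area=float(reference_area),
        n_cycles=len(intervals),
        period_defined=True,
    )


def bending_rate(
    phi: np.ndarray,
    threshold: float = 40.0,
    sweep: tuple[int, int] = (20, 90),
) -> pd.DataFrame:
    """Count lateral bending events per side over a range of |phi| thresholds.

    An event is a maximal run of consecutive frames with |phi| above the
    threshold and constant sign (left = positive phi).  Returns a table
    indexed by threshold with columns ``left``/``right``; the row at
    ``threshold`` is the headline rate.
    """
    phi = np.asarray(phi, dtype=float)
    thresholds = sorted(set(range(sweep[0], sweep[1] + 1, 5)) | {int(threshold)})
    rows = []
    for th in thresholds:
        left = _count_events(phi, th, side=+1)
        right = _count_events(phi, th, side=-1)
        rows.append({"threshold": th, "left": left, "right": right})
    return pd.DataFrame(rows).set_index("threshold")


def _count_events(phi: np.ndarray, threshold: float, side: int) -> int:
    above = np.where(np.isfinite(phi), side * phi > threshold, False)
    return int(np.diff(np.concatenate(([0], above.view(np.int8)))).clip(min=0).sum())


def stop_go_segmentation(
    track_set: TrackSet,
    params: StopGoParams | None = None,
    fps: float | None = None,
    tracks: list[Track] | None = None,
) -> StopGoMatrix:
    """Stop/go indicator matrices for all (or selected) tracks.

    Speed is the centroid displacement accumulated over ``t_window`` frames;
    a frame is go when that displacement exceeds ``v`` px and |phi| < beta;
    go runs shorter than ``t_go`` frames are erased.  Tracks shorter than
    the window are entirely stop.
    """
    params = params or track_set.config.stop_go
    T = track_set.n_frames
    tracks = tracks if tracks is not None else track_set.tracks
    go = np.zeros((T, len(tracks)), dtype=bool)
    for j, tr in enumerate(tracks):
        pos = _positions(tr, T, "centroid")
        phi = np.array(
            [
                tr.states[f].phi if f in tr.states else np.nan
                for f in range(T)
            ]
        )
        go[:, j] = _go_indicator(pos, phi, params)
    return StopGoMatrix(go=go, stop=~go, track_ids=[t.id for t in tracks])


def _go_indicator(
    pos: np.ndarray, phi: np.ndarray, p: StopGoParams
) -> np.ndarray:
    T = len(pos)
    w = p.t_window
    disp = np.zeros(T)
    valid = np.isfinite(pos[:, 0])
    if valid.sum() < 2 or T <= w:
        return np.zeros(T, dtype=bool)
    for t in range(T):
        a = max(t - w, 0)
        d = np.linalg.norm(pos[t] - pos[a])
        if t < w:  # scale the shorter leading window to window units
            d = d * (w / max(t, 1))
        disp[t] = d if np.isfinite(d) else 0.0
    calm = np.where(np.isfinite(phi), np.abs(phi) < p.beta, False)
    go = (disp > p.v) & calm & valid
    return _erase_short_runs(go, p.t_go)


def _erase_short_runs(indicator: np.ndarray, min_len: int) -> np.ndarray:
    out = indicator.copy()
    t = 0
    T = len(out)
    while t < T:
        if out[t]:
            start = t
            while t < T and out[t]:
                t += 1
            if t - start < min_len:
                out[start:t] = False
        else:
            t += 1
    return out
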
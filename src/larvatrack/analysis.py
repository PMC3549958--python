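"""Cohort-level analysis: feature matrices, classical MDS, group summaries.

Per-feature tables are T x N (rows = time steps, columns = animals), so each
animal is a T-dimensional vector per feature.  Cohorts are embedded in 2D by
classical (Torgerson) metric multidimensional scaling of the Euclidean
distance matrix between animal vectors: double-centre the squared-distance
matrix, take the top-two spectral coordinates.  Classical MDS is
deterministic (no iterative stress majorisation), so embeddings reproduce
without seeds, up to rotation/reflection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import bending_rate, kinematics
from .tracking import Track, TrackSet

_FEATURES = ("area", "phi", "row", "col")


@dataclass
class MdsEmbedding:
    """2D classical-MDS coordinates of N animals."""

    coords: np.ndarray        # (N, 2), centred at the origin
    eigenvalues: np.ndarray   # all N eigenvalues of the centred matrix, descending
    labels: list | None = None


def _state_value(state, feature: str) -> float:
    if feature == "area":
        return float(state.area)
    if feature == "phi":
        return float(state.phi)
    if feature == "row":
        return float(state.centroid[0])
    if feature == "col":
        return float(state.centroid[1])
    raise ValueError(f"unknown feature {feature!r} (one of {_FEATURES})")


def build_feature_matrix(
    track_set: TrackSet,
    feature: str,
    frame_range: tuple[int, int] | None = None,
    tracks: list[Track] | None = None,
) -> pd.DataFrame:
    """T x N table of one feature over a frame range (animals as columns).

    Every selected track must cover the whole range; offenders are listed in
    the raised error.
    """
    tracks = tracks if tracks is not None else track_set.tracks
    if frame_range is None:
        frame_range = (0, track_set.n_frames)
    lo, hi = frame_range
    offenders = [
        tr.id
        for tr in tracks
        if any(f not in tr.states for f in range(lo, hi))
    ]
    if offenders:
        raise ValueError(
            f"tracks with gaps in frames [{lo}, {hi}): {offenders}"
        )
    data = {
        tr.id: [_state_value(tr.states[f], feature) for f in range(lo, hi)]
        for tr in tracks
    }
    return pd.DataFrame(data, index=pd.RangeIndex(lo, hi, name="frame"))


def mds_embed(
    matrix: pd.DataFrame | np.ndarray, labels: list | None = None
) -> MdsEmbedding:
    """Classical (Torgerson) MDS of animal columns into two dimensions.

    Euclidean distances between columns are double-centred
    (B = -1/2 J D^2 J) and the two largest-eigenvalue spectral coordinates
    are returned.  Negative trailing eigenvalues diagnose non-Euclidean
    input.  Signs are fixed so each axis has a positive maximal-|coordinate|
    entry, making the output reproducible.
    """
    X = np.asarray(matrix, dtype=float).T  # animals as rows
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 animals for a 2D embedding")
    sq = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ sq @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    coords = evecs[:, :2] * np.sqrt(np.clip(evals[:2], 0.0, None))
    for d in range(2):
        i = np.argmax(np.abs(coords[:, d]))
        if coords[i, d] < 0:
            coords[:, d] = -coords[:, d]
    if labels is None and isinstance(matrix, pd.DataFrame):
        labels = list(matrix.columns)
    return MdsEmbedding(coords=coords, eigenvalues=evals, labels=labels)


def summarize_groups(
    groups: dict[str, TrackSet],
    mm_per_px: float | None = None,
    tracks_by_group: dict[str, list[Track]] | None = None,
) -> pd.DataFrame:
    """Median +/- SD of area, bending angle and total distance per cohort.

    Each animal is first reduced to scalars — median body area (px^2), mean
    bending angle (deg) and accumulated mid-landmark travel distance (mm
    when a scale is given, else px) — then each group reports the median
    and standard deviation of those scalars.
    """
    rows = []
    for label, ts in groups.items():
        tracks = (
            tracks_by_group[label]
            if tracks_by_group is not None
            else ts.complete_tracks() or ts.tracks
        )
        if not tracks:
            raise ValueError(f"group {label!r} has no tracks")
        areas, phis, dists = [], [], []
        for tr in tracks:
            st = list(tr.states.values())
            areas.append(np.median([s.area for s in st]))
            phi = [s.phi for s in st if np.isfinite(s.phi)]
            phis.append(np.mean(phi) if phi else np.nan)
            kin = kinematics(
                tr, ts.n_frames, ts.config.fps, mm_per_px=mm_per_px
            )
            acc = kin.accumulated[np.isfinite(kin.accumulated)]
            dists.append(acc[-1] if acc.size else 0.0)
        rows.append(
            {
                "group": label,
                "n": len(tracks),
                "area_median": float(np.median(areas)),
                "area_sd": float(np.std(areas)),
                "phi_median": float(np.nanmedian(phis)),
                "phi_sd": float(np.nanstd(phis)),
                "distance_median": float(np.median(dists)),
                "distance_sd": float(np.std(dists)),
            }
        )
    return pd.DataFrame(rows).set_index("group")


def discretize_distribution(
    values: np.ndarray, bin_edges: np.ndarray
) -> pd.DataFrame:
    """Histogram table over right-open bins [a, b) (final bin closed).

    Raises on non-monotone edges.  The counts sum to the number of values
    inside the edge range.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    values = np.asarray(values, dtype=float)
    counts, _ = np.histogram(values, bins=edges)
    return pd.DataFrame(
        {"left": edges[:-1], "right": edges[1:], "count": counts}
    )
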
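"""Movie reading, table writing and overlay rendering.

All tables are CSV in the T x N layout (rows = time steps, columns =
animals, header = animal ids); frames without a value stay empty (not
zero).  A JSON manifest records the configuration and seed so a run can be
reproduced byte for byte.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Iterator

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .analysis import _state_value
from .config import RunConfig
from .tracking import TrackSet

_FRAME_EXTS = {".png", ".tif", ".tiff"}

FEATURES_DEFAULT = ("area", "phi", "row", "col")


def read_movie(path: str | Path) -> Iterator[np.ndarray]:
    """Iterate 8-bit grey frames from a directory of PNG/TIFF files (in
    lexicographic name order) or a multi-page TIFF.

    RGB frames are converted to grey with a warning; frames of differing
    shapes raise.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _FRAME_EXTS
        )
        if not files:
            raise ValueError(f"no PNG/TIFF frames in {path}")
        shape = None
        for f in files:
            try:
                frame = iio.imread(f)
            except Exception as exc:
                raise ValueError(f"unreadable frame {f.name}: {exc}") from exc
            frame = _to_grey(frame, f.name)
            if shape is None:
                shape = frame.shape
            elif frame.shape != shape:
                raise ValueError(
                    f"mixed frame shapes: {f.name} is {frame.shape}, expected {shape}"
                )
            yield frame
    elif path.suffix.lower() in (".tif", ".tiff"):
        stack = tifffile.imread(path)
        if stack.ndim == 2:
            stack = stack[None]
        for i in range(stack.shape[0]):
            yield _to_grey(np.asarray(stack[i]), f"{path.name}[{i}]")
    else:
        raise ValueError(f"unsupported movie path: {path}")


def _to_grey(frame: np.ndarray, name: str) -> np.ndarray:
    if frame.ndim == 3:
        warnings.warn(f"{name}: RGB input converted to grey", stacklevel=3)
        frame = frame[..., :3].mean(axis=2)
    if frame.dtype != np.uint8:
        frame = np.clip(frame, 0, 255).astype(np.uint8)
    return frame


def write_frames(frames: np.ndarray, out_dir: str | Path) -> list[Path]:
    """Write a (T, H, W) stack as numbered PNG frames."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames):
        p = out / f"frame_{i:06d}.png"
        iio.imwrite(p, frame)
        paths.append(p)
    return paths


def write_feature_tables(
    track_set: TrackSet,
    out_dir: str | Path,
    features: tuple[str, ...] = FEATURES_DEFAULT,
) -> dict[str, Path]:
    """One CSV per feature in T x N layout, a collision-flag table, a
    collision-event log and a JSON manifest with the run configuration."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    T = track_set.n_frames
    ids = [tr.id for tr in track_set.tracks]
    for feature in features:
        cols = {}
        for tr in track_set.tracks:
            vals = np.full(T, np.nan)
            for f in range(T):
                s = tr.states.get(f)
                if s is not None:
                    vals[f] = _state_value(s, feature)
            cols[tr.id] = vals
        df = pd.DataFrame(cols, index=pd.RangeIndex(T, name="frame"))
        p = out / f"{feature}.csv"
        df.to_csv(p, float_format="%.6g")
        written[feature] = p

    coll = pd.DataFrame(
        {
            tr.id: [
                (
                    int(tr.states[f].collision)
                    if f in tr.states
                    else np.nan
                )
                for f in range(T)
            ]
            for tr in track_set.tracks
        },
        index=pd.RangeIndex(T, name="frame"),
    )
    p = out / "collision.csv"
    coll.to_csv(p, float_format="%.0f")
    written["collision"] = p

    events = pd.DataFrame(
        [
            {
                "frame_start": ev.frame_start,
                "frame_end": ev.frame_end,
                "id1": ev.participants[0],
                "id2": ev.participants[-1],
                "resolved": int(ev.resolved),
            }
            for ev in track_set.events
        ],
        columns=["frame_start", "frame_end", "id1", "id2", "resolved"],
    )
    p = out / "collision_events.csv"
    events.to_csv(p, index=False)
    written["collision_events"] = p

    manifest = {
        "n_frames": T,
        "track_ids": ids,
        "config": track_set.config.to_dict(),
    }
    p = out / "manifest.json"
    p.write_text(json.dumps(manifest, indent=2, default=float) + "\n")
    written["manifest"] = p
    return written


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Reload a T x N feature CSV with animal-id columns."""
    df = pd.read_csv(path, index_col="frame")
    df.columns = df.columns.astype(int)
    return df


# Fig-style marker colours: head green, centre red, tail blue.
_HEAD = np.array([0, 200, 0], dtype=np.uint8)
_MID = np.array([220, 0, 0], dtype=np.uint8)
_TAIL = np.array([0, 80, 255], dtype=np.uint8)
_CONTOUR = np.array([230, 210, 0], dtype=np.uint8)
_SPINE = np.array([255, 255, 255], dtype=np.uint8)
_TRAIL = np.array([0, 160, 200], dtype=np.uint8)
_COLLIDE = np.array([255, 0, 255], dtype=np.uint8)


def render_overlay(
    frames: np.ndarray,
    track_set: TrackSet,
    out_dir: str | Path | None = None,
    trail: int = 50,
) -> np.ndarray:
    """Annotated RGB frames: contour, spine, head/centre/tail markers,
    trajectory trails and collision highlights.

    A non-interactive replacement for a GUI review tool; returns the RGB
    stack and optionally writes numbered PNGs.
    """
    T = len(frames)
    H, W = frames[0].shape
    rgb = np.repeat(np.asarray(frames)[..., None], 3, axis=3).copy()
    for tr in track_set.tracks:
        cen = tr.centroids(T)
        for t in range(T):
            s = tr.states.get(t)
            if s is None:
                continue
            img = rgb[t]
            b = s.contour.boundary
            img[b[:, 0] % H, b[:, 1] % W] = _COLLIDE if s.collision else _CONTOUR
            if s.spine is not None:
                sp = np.rint(s.spine.points).astype(int)
                ok = (sp[:, 0] >= 0) & (sp[:, 0] < H) & (sp[:, 1] >= 0) & (sp[:, 1] < W)
                img[sp[ok, 0], sp[ok, 1]] = _SPINE
            for p, colour in (
                (s.head, _HEAD),
                (s.mid, _MID),
                (s.tail, _TAIL),
            ):
                if p is not None:
                    _draw_dot(img, p, colour)
            past = cen[max(t - trail, 0) : t + 1]
            past = past[np.isfinite(past[:, 0])]
            pp = np.rint(past).astype(int)
            ok = (pp[:, 0] >= 0) & (pp[:, 0] < H) & (pp[:, 1] >= 0) & (pp[:, 1] < W)
            img[pp[ok, 0], pp[ok, 1]] = _TRAIL
    if out_dir is not None:
        write_frames(rgb, out_dir)
    return rgb


def _draw_dot(img: np.ndarray, p: np.ndarray, colour: np.ndarray, r: int = 1) -> None:
    H, W = img.shape[:2]
    r0, c0 = int(round(p[0])), int(round(p[1]))
    for dr in range(-r, r + 1):
        for dc in range(-r, r + 1):
            rr, cc = r0 + dr, c0 + dc
            if 0 <= rr < H and 0 <= cc < W:
                img[rr, cc] = colour
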
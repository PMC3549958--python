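"""Synthetic FTIR-style movie generator with exhaustive ground truth.

Renders dark-background / bright-animal 8-bit movies that reproduce the
image statistics a frustrated-total-internal-reflection rig delivers: a
large uniform dark background, bright larval bodies with a strongly bimodal
grey-value histogram, a darker head blob at the anterior end, a
posterior-to-anterior travelling width wave that makes the projected body
area oscillate with the peristaltic period, scripted head casts, stop/go
schedules, and scripted two-animal collisions.  Every frame comes with full
ground truth (midline, landmarks, head end, bending angle, area, go state,
collision participation, optionally per-animal masks), so every stage of
the tracking pipeline can be validated without any hardware.

The body model is a midline anchored at the tail tip: local heading
``theta(u) = heading + B(t) * g(u)`` with a bend profile ``g`` confined to
the anterior half, integrated over arc length and swept with a symmetric,
tapered width profile.  Bend amplitudes are calibrated numerically so that
a scheduled head cast reaches its target bending angle phi exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy import ndimage
from scipy.optimize import brentq
from scipy.spatial import cKDTree

from .geometry import bending_angle

_WAVE_PHASE_SPAN = 0.25  # fraction of a wavelength across the body


@dataclass(frozen=True)
class BendEvent:
    """One scheduled head cast: phi ramps 0 -> target -> 0 over the event."""

    start: int
    end: int
    phi_deg: float  # signed target bending angle; positive = left


@dataclass(frozen=True)
class LarvaSpec:
    """Shape and behaviour of one synthetic larva.

    ``body_length`` presets 25/40/75/170 px correspond to the four imaging
    resolutions at which a third-instar animal spans that many pixels.
    ``peristalsis_amplitude`` is the relative amplitude of the projected
    body-area oscillation; the width wave is scaled so the area series hits
    it exactly.  ``go_intervals=None`` means the animal crawls throughout.
    """

    body_length: float = 40.0
    width_frac: float = 0.15
    speed: float = 2.0                       # px/frame while in a go phase
    peristalsis_period: int = 7              # frames per contraction cycle
    peristalsis_amplitude: float = 0.04
    head_darkness: float = 0.5               # fraction of fg-bg removed at the head blob
    heading_noise_deg: float = 2.0
    bend_schedule: tuple[BendEvent, ...] = ()
    go_intervals: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        if self.body_length <= 0:
            raise ValueError("body_length must be positive")
        if not 0 <= self.peristalsis_amplitude <= 0.5:
            raise ValueError("peristalsis_amplitude must be in [0, 0.5]")

    @property
    def width(self) -> float:
        return self.width_frac * self.body_length


@dataclass(frozen=True)
class CollisionScript:
    """Scripted pairwise touch: larvae ``pair`` overlap ``contact_fraction``
    of a body length for ``duration`` frames starting at ``start``."""

    pair: tuple[int, int] = (0, 1)
    start: int = 30
    duration: int = 5
    contact_fraction: float = 0.3
    approach: int = 20
    crawl_over: bool = False


@dataclass(frozen=True)
class SceneSpec:
    """A complete synthetic recording session."""

    larvae: tuple[LarvaSpec, ...]
    n_frames: int = 100
    arena: tuple[int, int] = (512, 512)
    fps: float = 10.0
    background: float = 28.0
    foreground: float = 180.0
    noise_sd: float = 2.0
    seed: int = 0
    separate_cells: bool = False             # confine each animal to its own cell
    script: CollisionScript | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.background <= 255 or not 0 <= self.foreground <= 255:
            raise ValueError("grey levels must lie in [0, 255]")
        if self.n_frames < 1 or not self.larvae:
            raise ValueError("scene needs at least one frame and one larva")

    @property
    def n_larvae(self) -> int:
        return len(self.larvae)


@dataclass
class GroundTruth:
    """Per-frame, per-animal truth for a rendered scene.

    Landmark/midline arrays are oriented head-first (index 0 = head tip).
    ``masks[t][i]`` (optional) is ``(bbox, local bool mask)``.
    """

    centroids: np.ndarray      # (T, N, 2) mask centroid (row, col)
    landmarks: np.ndarray      # (T, N, 7, 2)
    midlines: np.ndarray       # (T, N, M, 2)
    phi: np.ndarray            # (T, N) signed degrees
    area: np.ndarray           # (T, N) rendered mask pixel count
    go: np.ndarray             # (T, N) bool, programmed go state
    collision: np.ndarray      # (T, N) bool
    fps: float
    masks: list | None = None

    @property
    def head(self) -> np.ndarray:
        """(T, N, 2) ground-truth head-tip positions."""
        return self.midlines[:, :, 0]


def _taper(u: np.ndarray, knee: float = 0.12) -> np.ndarray:
    """Width taper: constant mid-body, rounded caps within ``knee`` of each
    tip.  The square root gives the cap a vertical tangent at the tip, so
    the rendered body keeps super-pixel width almost to the midline end and
    its mask spans the full programmed body length."""
    return np.clip(
        np.sqrt(np.clip(np.sin(np.pi * u), 0.0, None) / np.sin(np.pi * knee)),
        0.0,
        1.0,
    )


def _bend_profile(u: np.ndarray) -> np.ndarray:
    """Anterior bend profile g(u): zero on the posterior body, smooth ramp
    across the neck (u 0.45-0.75), then the head section swings rigidly —
    this keeps head casts gentle curves rather than tight curls."""
    x = np.clip((u - 0.45) / 0.3, 0.0, 1.0)
    return x * x * (3 - 2 * x)


class _LarvaSim:
    """Kinematic state and renderer for one animal."""

    N_MID = 41

    def __init__(
        self,
        spec: LarvaSpec,
        anchor: np.ndarray,
        heading: float,
        rng: np.random.Generator,
        cell: tuple[float, float, float, float] | None = None,
    ) -> None:
        self.spec = spec
        self.anchor = np.asarray(anchor, dtype=float)  # tail tip (row, col)
        self.heading = float(heading)
        self.rng = rng
        self.cell = cell  # (rmin, cmin, rmax, cmax) wander bounds
        self.u = np.linspace(0.0, 1.0, self.N_MID)  # 0 = tail, 1 = head
        self.g = _bend_profile(self.u)
        self.taper = _taper(self.u)
        # Area-amplitude attenuation of the travelling width wave.
        ph = 2 * np.pi * _WAVE_PHASE_SPAN * self.u
        w = self.taper
        self._attn = float(
            np.hypot((w * np.cos(ph)).sum(), (w * np.sin(ph)).sum()) / w.sum()
        )
        self._phi_cal = self._calibrate_bend()

    # -- bend calibration -------------------------------------------------
    def _phi_of_B(self, B: float) -> float:
        pts = self._midline_points(B, np.zeros(2), 0.0)
        lm = _arc_landmarks(pts[::-1], 7)  # head-first
        try:
            phi, _ = bending_angle(lm[1], lm[3], lm[5])
        except ValueError:
            phi = 0.0
        return phi

    def _calibrate_bend(self) -> Callable[[float], float]:
        # Positive curvature B bends the head clockwise on screen, i.e. to
        # the animal's right (negative phi): solve on |phi| and flip sign.
        def bend_for_phi(phi_target: float) -> float:
            if phi_target == 0:
                return 0.0
            f = lambda B: abs(self._phi_of_B(B)) - abs(phi_target)
            try:
                B = brentq(f, 0.0, 4.0, xtol=1e-4)
            except ValueError:
                B = 4.0
            return np.sign(phi_target) * np.sign(self._phi_of_B(1.0)) * B

        return bend_for_phi

    # -- schedule ----------------------------------------------------------
    def is_go(self, t: int) -> bool:
        iv = self.spec.go_intervals
        if iv is None:
            return True
        return any(a <= t < b for a, b in iv)

    def bend_B(self, t: int) -> float:
        B = 0.0
        for ev in self.spec.bend_schedule:
            if ev.start <= t < ev.end:
                frac = (t - ev.start) / max(ev.end - ev.start - 1, 1)
                target = ev.phi_deg * np.sin(np.pi * frac)
                B += self._phi_cal(target)
        return B

    # -- kinematics --------------------------------------------------------
    def step(self, t: int) -> None:
        if self.is_go(t):
            d = np.array([np.sin(self.heading), np.cos(self.heading)])
            self.anchor = self.anchor + self.spec.speed * d
            self.heading += np.radians(
                self.rng.normal(0.0, self.spec.heading_noise_deg)
            )
        if self.cell is not None:
            self._steer_into_cell()

    def _steer_into_cell(self) -> None:
        rmin, cmin, rmax, cmax = self.cell
        L = self.spec.body_length
        centre = np.array([(rmin + rmax) / 2, (cmin + cmax) / 2])
        margin = 0.9 * L
        head = self.anchor + L * np.array(
            [np.sin(self.heading), np.cos(self.heading)]
        )
        near_wall = (
            min(head[0] - rmin, rmax - head[0], head[1] - cmin, cmax - head[1])
            < margin
        )
        if near_wall:
            to_centre = centre - self.anchor
            target = np.arctan2(to_centre[0], to_centre[1])
            diff = (target - self.heading + np.pi) % (2 * np.pi) - np.pi
            self.heading += np.clip(diff, -np.radians(9.0), np.radians(9.0))

    def _midline_points(
        self, B: float, anchor: np.ndarray, heading: float
    ) -> np.ndarray:
        """Tail-first midline: integrate local heading over arc length."""
        theta = heading + B * self.g
        ds = self.spec.body_length / (self.N_MID - 1)
        mid_theta = 0.5 * (theta[:-1] + theta[1:])
        steps = ds * np.column_stack((np.sin(mid_theta), np.cos(mid_theta)))
        return anchor + np.vstack((np.zeros(2), np.cumsum(steps, axis=0)))

    def midline(self, t: int) -> np.ndarray:
        return self._midline_points(self.bend_B(t), self.anchor, self.heading)

    def halfwidths(self, t: int) -> np.ndarray:
        """Per-midline-sample half-width including the peristaltic wave."""
        sp = self.spec
        base = 0.5 * sp.width * self.taper
        if sp.peristalsis_amplitude == 0:
            return base
        amp = sp.peristalsis_amplitude / self._attn
        phase = 2 * np.pi * (t / sp.peristalsis_period - _WAVE_PHASE_SPAN * self.u)
        return base * (1.0 + amp * np.sin(phase))

    # -- rendering ---------------------------------------------------------
    def render(
        self, t: int, shape: tuple[int, int]
    ) -> tuple[tuple[int, int, int, int], np.ndarray, np.ndarray]:
        """Coverage and head-blob darkening fields on the body's bbox."""
        mid = self.midline(t)
        hw = self.halfwidths(t)
        dense, hw_dense = _densify_with_widths(mid, hw, step=0.5)
        hw_max = hw.max()
        r0 = max(int(np.floor(dense[:, 0].min() - hw_max - 2)), 0)
        c0 = max(int(np.floor(dense[:, 1].min() - hw_max - 2)), 0)
        r1 = min(int(np.ceil(dense[:, 0].max() + hw_max + 3)), shape[0])
        c1 = min(int(np.ceil(dense[:, 1].max() + hw_max + 3)), shape[1])
        if r1 <= r0 or c1 <= c0:
            return (0, 0, 0, 0), np.zeros((0, 0)), np.zeros((0, 0))
        rr, cc = np.mgrid[r0:r1, c0:c1]
        pix = np.column_stack((rr.ravel(), cc.ravel())).astype(float)
        dist, idx = cKDTree(dense).query(pix)
        cov = np.clip(hw_dense[idx] - dist + 0.5, 0.0, 1.0).reshape(r1 - r0, c1 - c0)

        # Dark head blob near the anterior tip (u ~ 0.84).
        arc = np.linspace(0, 1, len(dense))
        centre = dense[np.searchsorted(arc, 0.84)]
        radius = 0.8 * 0.5 * self.spec.width
        d_blob = np.linalg.norm(pix - centre, axis=1)
        blob = np.clip(radius - d_blob + 0.5, 0.0, 1.0).reshape(cov.shape)
        blob *= cov >= 0.9  # darken only the covered body, not the rim
        return (r0, c0, r1, c1), cov, blob


def _densify_with_widths(
    points: np.ndarray, widths: np.ndarray, step: float
) -> tuple[np.ndarray, np.ndarray]:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    arc = np.concatenate(([0.0], np.cumsum(seg)))
    n = max(int(arc[-1] / step), 2)
    s = np.linspace(0, arc[-1], n)
    r = np.interp(s, arc, points[:, 0])
    c = np.interp(s, arc, points[:, 1])
    w = np.interp(s, arc, widths)
    return np.column_stack((r, c)), w


def _arc_landmarks(points: np.ndarray, n: int) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    arc = np.concatenate(([0.0], np.cumsum(seg)))
    s = np.linspace(0, arc[-1], n)
    r = np.interp(s, arc, points[:, 0])
    c = np.interp(s, arc, points[:, 1])
    return np.column_stack((r, c))


def _initial_placement(
    spec: SceneSpec, rng: np.random.Generator
) -> list[tuple[np.ndarray, float, tuple | None]]:
    """Anchors, headings and (optionally) wander cells for all larvae."""
    H, W = spec.arena
    n = spec.n_larvae
    out: list[tuple[np.ndarray, float, tuple | None]] = []
    if spec.script is not None:
        return out  # scripted scenes place analytically per frame
    if spec.separate_cells:
        per_side = int(np.ceil(np.sqrt(n)))
        ch, cw = H / per_side, W / per_side
        for i in range(n):
            L = spec.larvae[i].body_length
            gr, gc = divmod(i, per_side)
            cell = (gr * ch, gc * cw, (gr + 1) * ch, (gc + 1) * cw)
            if min(ch, cw) < 2.4 * L:
                raise ValueError("arena too small for non-overlapping cells")
            anchor = np.array(
                [
                    rng.uniform(cell[0] + 1.1 * L, cell[2] - 1.1 * L),
                    rng.uniform(cell[1] + 1.1 * L, cell[3] - 1.1 * L),
                ]
            )
            out.append((anchor, rng.uniform(0, 2 * np.pi), cell))
        return out
    placed: list[np.ndarray] = []
    for i in range(n):
        L = spec.larvae[i].body_length
        for _ in range(400):
            anchor = np.array(
                [rng.uniform(1.2 * L, H - 1.2 * L), rng.uniform(1.2 * L, W - 1.2 * L)]
            )
            if all(np.linalg.norm(anchor - p) > 2.4 * L for p in placed):
                break
        else:
            raise ValueError("overlapping initial placement: arena too crowded")
        placed.append(anchor)
        out.append((anchor, rng.uniform(0, 2 * np.pi), (0, 0, H, W)))
    return out


def _script_positions(
    spec: SceneSpec, t: int
) -> list[tuple[np.ndarray, float]] | None:
    """Anchors/headings for a scripted two-larva collision scene at frame t."""
    sc = spec.script
    if sc is None:
        return None
    la = spec.larvae[sc.pair[0]]
    L, wdt = la.body_length, la.width
    H, W = spec.arena
    base_row = H / 2.0
    drift = 0.5 * t  # both animals keep crawling slowly
    a_col = 0.15 * W + drift

    lat_far = 3.0 * wdt + 6.0
    lat_contact = 0.15 * wdt if sc.crawl_over else wdt * (
        0.95 - 0.5 * min(sc.contact_fraction, 1.0)
    )
    t0 = sc.start - sc.approach
    if t < t0:
        lat = lat_far
    elif t < sc.start:
        lat = lat_far + (lat_contact - lat_far) * (t - t0) / sc.approach
    elif t < sc.start + sc.duration:
        lat = lat_contact
    elif t < sc.start + sc.duration + sc.approach:
        lat = lat_contact + (lat_far - lat_contact) * (
            t - sc.start - sc.duration
        ) / sc.approach
    else:
        lat = lat_far
    b_col = a_col + (1.0 - min(sc.contact_fraction, 1.0)) * L
    return [
        (np.array([base_row, a_col]), 0.0),
        (np.array([base_row + lat, b_col]), 0.0),
    ]


def render_scene(
    spec: SceneSpec, keep_masks: bool = False
) -> tuple[np.ndarray, GroundTruth]:
    """Render a scene to an (T, H, W) uint8 movie plus its ground truth.

    Deterministic for a given ``spec`` (including its seed).
    """
    H, W = spec.arena
    T, N = spec.n_frames, spec.n_larvae
    root = np.random.SeedSequence([spec.seed, 2718])
    noise_rng = np.random.default_rng(root.spawn(1)[0])
    larva_rngs = [np.random.default_rng(s) for s in root.spawn(N + 1)[1:]]
    place_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 314]))

    placement = _initial_placement(spec, place_rng)
    sims = []
    for i, lspec in enumerate(spec.larvae):
        if spec.script is not None:
            sims.append(_LarvaSim(lspec, np.zeros(2), 0.0, larva_rngs[i]))
        else:
            anchor, heading, cell = placement[i]
            sims.append(_LarvaSim(lspec, anchor, heading, larva_rngs[i], cell))

    frames = np.empty((T, H, W), dtype=np.uint8)
    gt = GroundTruth(
        centroids=np.zeros((T, N, 2)),
        landmarks=np.zeros((T, N, 7, 2)),
        midlines=np.zeros((T, N, _LarvaSim.N_MID, 2)),
        phi=np.zeros((T, N)),
        area=np.zeros((T, N), dtype=int),
        go=np.zeros((T, N), dtype=bool),
        collision=np.zeros((T, N), dtype=bool),
        fps=spec.fps,
        masks=[] if keep_masks else None,
    )
    fg_gain = spec.foreground - spec.background

    for t in range(T):
        scripted = _script_positions(spec, t)
        if scripted is not None:
            for sim, (anchor, heading) in zip(sims, scripted):
                sim.anchor, sim.heading = anchor, heading
        frame = np.full((H, W), spec.background, dtype=float)
        frame_masks = []
        bboxes = []
        for i, sim in enumerate(sims):
            bbox, cov, blob = sim.render(t, (H, W))
            r0, c0, r1, c1 = bbox
            body = spec.background + cov * fg_gain - blob * (
                sim.spec.head_darkness * fg_gain
            )
            frame[r0:r1, c0:c1] = np.maximum(frame[r0:r1, c0:c1], body)
            mask = cov >= 0.5
            bboxes.append(bbox)
            frame_masks.append(mask)

            mid = sim.midline(t)[::-1]  # head-first
            gt.midlines[t, i] = mid
            gt.landmarks[t, i] = _arc_landmarks(mid, 7)
            lm = gt.landmarks[t, i]
            try:
                gt.phi[t, i], _ = bending_angle(lm[1], lm[3], lm[5])
            except ValueError:
                gt.phi[t, i] = 0.0
            gt.area[t, i] = int(mask.sum())
            gt.go[t, i] = sim.is_go(t)
            if mask.any():
                rr, cc = np.nonzero(mask)
                gt.centroids[t, i] = (rr.mean() + r0, cc.mean() + c0)
        _mark_collisions(gt, t, bboxes, frame_masks)
        if keep_masks:
            gt.masks.append(
                [(bboxes[i], frame_masks[i].copy()) for i in range(N)]
            )
        if spec.noise_sd > 0:
            frame = frame + noise_rng.normal(0.0, spec.noise_sd, size=(H, W))
        frames[t] = np.clip(np.rint(frame), 0, 255).astype(np.uint8)
        for sim in sims:
            if scripted is None:
                sim.step(t)
    return frames, gt


def _mark_collisions(gt: GroundTruth, t: int, bboxes: list, masks: list) -> None:
    """Flag animals whose rendered masks touch (8-connected) at frame t."""
    n = len(bboxes)
    for i in range(n):
        for j in range(i + 1, n):
            ri0, ci0, ri1, ci1 = bboxes[i]
            rj0, cj0, rj1, cj1 = bboxes[j]
            r0, c0 = max(ri0, rj0), max(ci0, cj0)
            r1, c1 = min(ri1, rj1), min(ci1, cj1)
            if r1 <= r0 or c1 <= c0:
                continue
            a = masks[i][r0 - ri0 : r1 - ri0, c0 - ci0 : c1 - ci0]
            b = masks[j][r0 - rj0 : r1 - rj0, c0 - cj0 : c1 - cj0]
            if (ndimage.binary_dilation(a, np.ones((3, 3))) & b).any():
                gt.collision[t, i] = True
                gt.collision[t, j] = True


def collision_scenario(
    contact_fraction: float,
    duration: int,
    n_frames: int | None = None,
    body_length: float = 40.0,
    crawl_over: bool | None = None,
    seed: int = 0,
    noise_sd: float = 2.0,
) -> SceneSpec:
    """Two-larva scene with a scripted touch of the given contact fraction.

    ``contact_fraction`` is the touched fraction of a body length; 1.0 with
    ``crawl_over`` makes the animals stack almost fully (the unresolvable
    class).
    """
    if not 0 < contact_fraction <= 1.0:
        raise ValueError("contact_fraction must be in (0, 1]")
    if crawl_over is None:
        crawl_over = contact_fraction >= 1.0
    approach = 20
    start = approach + 15
    if n_frames is None:
        n_frames = start + duration + approach + 15
    larva = LarvaSpec(
        body_length=body_length, speed=0.5, heading_noise_deg=0.0
    )
    width = larva.width
    arena_h = int(6 * width + 12 + 2 * body_length)
    arena_w = int(0.5 * n_frames + 2.4 * body_length + 60)
    return SceneSpec(
        larvae=(larva, larva),
        n_frames=n_frames,
        arena=(max(arena_h, 96), arena_w),
        noise_sd=noise_sd,
        seed=seed,
        script=CollisionScript(
            pair=(0, 1),
            start=start,
            duration=duration,
            contact_fraction=contact_fraction,
            approach=approach,
            crawl_over=crawl_over,
        ),
    )


def make_wander_scene(
    n_larvae: int,
    n_frames: int,
    body_length: float = 40.0,
    arena: tuple[int, int] | None = None,
    seed: int = 0,
    separate_cells: bool = True,
    with_pauses: bool = True,
    noise_sd: float = 2.0,
) -> SceneSpec:
    """Multi-larva scene with randomised stop/go schedules and head casts.

    Each animal alternates go runs (40-80 frames) with pauses (16-30 frames)
    during which it performs one head cast of 25-70 degrees to a random
    side.  With ``separate_cells`` the animals wander in disjoint arena
    cells and are guaranteed collision-free.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 99]))
    larvae = []
    for _ in range(n_larvae):
        if with_pauses:
            go, bends = _random_schedule(n_frames, rng)
        else:
            go, bends = None, ()
        larvae.append(
            LarvaSpec(
                body_length=body_length,
                speed=0.05 * body_length,
                go_intervals=go,
                bend_schedule=bends,
            )
        )
    if arena is None:
        per_side = int(np.ceil(np.sqrt(n_larvae)))
        side = int(np.ceil(per_side * 2.6 * body_length)) + 8
        arena = (side, side)
    return SceneSpec(
        larvae=tuple(larvae),
        n_frames=n_frames,
        arena=arena,
        seed=seed,
        separate_cells=separate_cells,
        noise_sd=noise_sd,
    )


def _random_schedule(
    n_frames: int, rng: np.random.Generator
) -> tuple[tuple[tuple[int, int], ...], tuple[BendEvent, ...]]:
    go: list[tuple[int, int]] = []
    bends: list[BendEvent] = []
    t = 0
    while t < n_frames:
        run = int(rng.integers(40, 81))
        go.append((t, min(t + run, n_frames)))
        t += run
        pause = int(rng.integers(16, 31))
        if t < n_frames and pause >= 12:
            side = rng.choice([-1.0, 1.0])
            target = float(rng.uniform(25, 70)) * side
            b0 = t + 2
            b1 = min(t + pause - 2, n_frames)
            if b1 - b0 >= 6:
                bends.append(BendEvent(start=b0, end=b1, phi_deg=target))
        t += pause
    return tuple(go), tuple(bends)


class PwmSource:
    """Simulated image source whose contrast depends on an illumination level.

    Emulates sweeping an LED's PWM duty cycle: a fixed scene (static bodies
    over a textured background) is re-exposed with a foreground gain that
    rises linearly to a configurable peak level and falls beyond it, so the
    Otsu separability eta is a unimodal function of the level with its
    maximum exactly at the peak.  Deterministic per level.
    """

    def __init__(
        self,
        peak: int = 100,
        shape: tuple[int, int] = (160, 160),
        seed: int = 0,
        background: float = 26.0,
        min_gain: float = 40.0,
        max_gain: float = 200.0,
    ) -> None:
        self.peak = int(peak)
        self.background = background
        self.min_gain = min_gain
        self.max_gain = max_gain
        # Texture spreads are chosen so eta stays mid-range at the peak:
        # near saturation d(eta)/d(gain) would shrink below the 8-bit
        # quantisation wiggle and adjacent levels could swap rank.
        rng = np.random.default_rng(np.random.SeedSequence([seed, 41]))
        self._bg_tex = rng.normal(0.0, 4.0, size=shape)
        self._body_tex = rng.normal(0.0, 9.0, size=shape)
        scene = make_wander_scene(
            2,
            1,
            body_length=0.2 * min(shape),
            arena=shape,
            seed=seed,
            with_pauses=False,
            noise_sd=0.0,
        )
        frames, gt = render_scene(replace(scene, foreground=255.0, background=0.0))
        self._cov = frames[0].astype(float) / 255.0

    def gain(self, p: int) -> float:
        """Foreground gain: tent curve peaking at the configured level.

        The floor ``min_gain`` keeps every level above the class-overlap
        regime, where Otsu's eta is non-monotone in the contrast gap, so
        the sweep curve is unimodal by construction.  The span is chosen so
        each level step moves the foreground by at least one grey level on
        both tent flanks; otherwise 8-bit quantisation could render
        neighbouring levels identically and blur the argmax.
        """
        if p <= self.peak:
            g = (p - 1) / max(self.peak - 1, 1)
        else:
            g = (255 - p) / max(255 - self.peak, 1)
        return self.min_gain + (self.max_gain - self.min_gain) * max(g, 0.0)

    def __call__(self, p: int) -> np.ndarray:
        g = self.gain(int(p))
        img = (
            self.background
            + self._bg_tex
            + self._cov * g
            + self._body_tex * (self._cov > 0.5)
        )
        return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def pwm_source(
    peak: int = 100, seed: int = 0, shape: tuple[int, int] = (160, 160)
) -> PwmSource:
    """Factory for a deterministic illumination-sweep image source."""
    return PwmSource(peak=peak, shape=shape, seed=seed)
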
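"""Independent oracles shared by the test modules."""

from __future__ import annotations

import numpy as np

from larvatrack.calibration import Histogram


def random_histogram(rng: np.random.Generator) -> Histogram:
    """Bimodal-ish random histogram (two discretised Gaussians + noise)."""
    counts = np.zeros(256, dtype=np.int64)
    levels = np.arange(256)
    for mean, sd, weight in (
        (rng.uniform(15, 80), rng.uniform(3, 20), rng.uniform(0.6, 0.95)),
        (rng.uniform(100, 230), rng.uniform(3, 25), None),
    ):
        w = weight if weight is not None else 1.0
        pdf = np.exp(-0.5 * ((levels - mean) / sd) ** 2)
        counts += np.rint(w * 10000 * pdf / pdf.sum()).astype(np.int64)
    counts += rng.integers(0, 3, size=256)
    return Histogram(counts=counts)


def brute_force_otsu(hist: Histogram) -> tuple[int, float]:
    """Threshold oracle: scan all candidates, class statistics from scratch."""
    p = hist.p
    levels = np.arange(256, dtype=float)
    best_k, best_sb = None, -1.0
    for k in range(255):
        w0 = p[: k + 1].sum()
        w1 = p[k + 1 :].sum()
        if w0 <= 0 or w1 <= 0:
            continue
        mu0 = (levels[: k + 1] * p[: k + 1]).sum() / w0
        mu1 = (levels[k + 1 :] * p[k + 1 :]).sum() / w1
        sb = w0 * w1 * (mu1 - mu0) ** 2
        if sb > best_sb * (1 + 1e-9) + 1e-15:
            best_sb, best_k = sb, k
    return best_k, best_sb


def arc_position(points: np.ndarray, q: np.ndarray) -> float:
    """Exact arc-length position of q along a polyline (segment projection)."""
    seg = np.diff(points, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    arc = np.concatenate(([0.0], seg_len.cumsum()))
    best_d, best_s = np.inf, 0.0
    for i in range(len(seg)):
        if seg_len[i] == 0:
            continue
        t = np.clip((q - points[i]) @ seg[i] / seg_len[i] ** 2, 0, 1)
        p = points[i] + t * seg[i]
        d = np.linalg.norm(q - p)
        if d < best_d:
            best_d, best_s = d, arc[i] + t * seg_len[i]
    return best_s


def landmark_spacing_deviation(points: np.ndarray, landmarks: np.ndarray) -> float:
    """Relative spread of consecutive landmark arc spacings along a spine."""
    pos = [arc_position(points, lm) for lm in landmarks]
    spacing = np.diff(pos)
    return float((spacing.max() - spacing.min()) / spacing.mean())
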
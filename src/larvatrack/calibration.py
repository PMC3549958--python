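"""Grey-value histogram statistics for illumination-quality calibration.

FTIR-style recordings show a bright animal on a large, nearly uniform dark
background, so the grey-value histogram is strongly bimodal and class
separability is a direct measure of image quality.  This module provides the
Otsu threshold together with its full class statistics (class probabilities,
class means, within/between-class variance and the separability measure
``eta = sigma2_between / sigma2_total``), the Weber contrast
``(mu1 - mu0) / mu0`` appropriate when background pixels dominate the frame,
and an illumination sweep that picks the simulated light level maximising
eta — the software analogue of tuning an LED's PWM duty cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

N_LEVELS = 256  # 8-bit grey values


@dataclass(frozen=True)
class Histogram:
    """Grey-value histogram of an 8-bit image.

    Attributes
    ----------
    counts : (256,) int array
        Pixel counts per grey level.
    p : (256,) float array
        Normalised frequencies ``counts / counts.sum()``.
    """

    counts: np.ndarray
    p: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (N_LEVELS,):
            raise ValueError(f"histogram must have {N_LEVELS} bins, got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("histogram counts must be non-negative")
        total = counts.sum()
        if total == 0:
            raise ValueError("empty histogram")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "p", counts / float(total))

    @property
    def n_pixels(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class OtsuResult:
    """Otsu threshold and the class statistics evaluated at it.

    The convention follows the usual formulation: background class
    ``C0 = {x <= k}``, foreground class ``C1 = {x >= k + 1}``.
    """

    k: int
    omega0: float
    omega1: float
    mu0: float
    mu1: float
    sigma2_within: float
    sigma2_between: float
    sigma2_total: float
    eta: float


@dataclass(frozen=True)
class ContrastReport:
    """Weber contrast ``(mu1 - mu0) / mu0`` for a thresholded histogram."""

    weber: float
    mu0: float
    mu1: float


@dataclass(frozen=True)
class CalibrationCurve:
    """Per-illumination-level Otsu quality records from a calibration sweep."""

    levels: np.ndarray        # evaluated illumination levels p
    thresholds: np.ndarray    # Otsu k per level (-1 where degenerate)
    etas: np.ndarray          # separability per level (0 where degenerate)
    best_p: int
    best_k: int

    def as_records(self) -> list[dict]:
        return [
            {"p": int(p), "k": int(k), "eta": float(e)}
            for p, k, e in zip(self.levels, self.thresholds, self.etas)
        ]


def compute_histogram(frame: np.ndarray) -> Histogram:
    """Histogram of an 8-bit grey frame.

    Raises
    ------
    ValueError
        If the frame is empty or holds values outside [0, 255].
    """
    arr = np.asarray(frame)
    if arr.size == 0:
        raise ValueError("empty image")
    if arr.dtype != np.uint8:
        if np.issubdtype(arr.dtype, np.floating) or arr.min() < 0 or arr.max() > 255:
            raise ValueError("frame must hold 8-bit values in [0, 255]")
        arr = arr.astype(np.uint8)
    counts = np.bincount(arr.ravel(), minlength=N_LEVELS)
    return Histogram(counts=counts)


def _class_stats(p: np.ndarray, k: int) -> tuple[float, float, float, float]:
    """(omega0, omega1, mu0, mu1) for background {<=k} / foreground {>k}."""
    levels = np.arange(N_LEVELS)
    w0 = float(p[: k + 1].sum())
    w1 = float(p[k + 1 :].sum())
    mu0 = float((levels[: k + 1] * p[: k + 1]).sum() / w0) if w0 > 0 else 0.0
    mu1 = float((levels[k + 1 :] * p[k + 1 :]).sum() / w1) if w1 > 0 else 0.0
    return w0, w1, mu0, mu1


def otsu_threshold(hist: Histogram) -> OtsuResult:
    """Threshold maximising the between-class variance.

    Scans every candidate threshold ``k`` (background = values <= k), picks
    the smallest ``k`` attaining the maximal ``sigma2_between`` and returns
    all class statistics at that threshold.

    Raises
    ------
    ValueError
        If fewer than two grey levels are occupied (``sigma2_total = 0``,
        eta undefined): "degenerate histogram".
    """
    p = hist.p
    occupied = np.nonzero(p)[0]
    if occupied.size < 2:
        raise ValueError("degenerate histogram: fewer than two occupied grey levels")

    levels = np.arange(N_LEVELS, dtype=float)
    mu_total = float((levels * p).sum())
    sigma2_total = float(((levels - mu_total) ** 2 * p).sum())

    # Cumulative formulation: omega(k) = sum_{i<=k} p_i, mu(k) = sum i*p_i.
    omega = np.cumsum(p)
    mu = np.cumsum(levels * p)
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma2_b = (mu_total * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma2_b = np.where((omega > 0) & (omega < 1), sigma2_b, -np.inf)

    # Smallest k attaining the maximum; zero-count plateaus between modes
    # give exact ties, so compare with a relative tolerance.
    best = sigma2_b.max()
    k = int(np.nonzero(sigma2_b >= best - 1e-9 * max(best, 1.0))[0][0])
    w0, w1, mu0, mu1 = _class_stats(p, k)
    sigma2_between = float(sigma2_b[k])
    var0 = float((((levels[: k + 1] - mu0) ** 2) * p[: k + 1]).sum() / w0)
    var1 = float((((levels[k + 1 :] - mu1) ** 2) * p[k + 1 :]).sum() / w1)
    sigma2_within = w0 * var0 + w1 * var1
    eta = sigma2_between / sigma2_total
    return OtsuResult(
        k=k,
        omega0=w0,
        omega1=w1,
        mu0=mu0,
        mu1=mu1,
        sigma2_within=sigma2_within,
        sigma2_between=sigma2_between,
        sigma2_total=sigma2_total,
        eta=eta,
    )


def weber_contrast(hist: Histogram, k: int) -> ContrastReport:
    """Weber contrast of the two histogram classes split at threshold ``k``.

    Appropriate when the background dominates the frame so the average
    luminance approximates the background luminance.

    Raises
    ------
    ValueError
        If either class is empty at ``k`` or the background mean is zero.
    """
    w0, w1, mu0, mu1 = _class_stats(hist.p, int(k))
    if w0 <= 0 or w1 <= 0:
        raise ValueError(f"empty class at threshold {k}")
    if mu0 == 0:
        raise ValueError("zero background luminance")
    return ContrastReport(weber=(mu1 - mu0) / mu0, mu0=mu0, mu1=mu1)


def calibrate_illumination(
    source: Callable[[int], np.ndarray],
    levels: Iterable[int] | Sequence[int] = range(1, 256),
) -> CalibrationCurve:
    """Sweep illumination levels and pick the one with the best separability.

    For every level ``p`` the source yields a frame; its Otsu threshold and
    eta are recorded.  Degenerate frames (a single occupied grey level) get
    ``eta = 0`` so a sweep always completes.  ``best_p`` is the smallest
    level attaining the maximal eta.
    """
    levels = np.asarray(list(levels), dtype=int)
    if levels.size == 0:
        raise ValueError("no illumination levels to evaluate")
    ks = np.full(levels.size, -1, dtype=int)
    etas = np.zeros(levels.size, dtype=float)
    for i, p in enumerate(levels):
        hist = compute_histogram(source(int(p)))
        try:
            res = otsu_threshold(hist)
        except ValueError:
            continue  # degenerate frame: eta stays 0
        ks[i] = res.k
        etas[i] = res.eta
    best_i = int(np.argmax(etas))  # first maximiser = lowest level on ties
    return CalibrationCurve(
        levels=levels,
        thresholds=ks,
        etas=etas,
        best_p=int(levels[best_i]),
        best_k=int(ks[best_i]),
    )
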
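"""Follicle-expansion morphometry from time-lapse stacks.

Each frame shows one follicle as a bright object on a dark background.
The pipeline thresholds each frame (Otsu by default), measures the
projected surface area of the largest connected component, fits the
logistic expansion curve

    A(t) = A0 + (Amax - A0) / (1 + exp(-k (t - t50)))

and calls rupture from a sustained post-peak contraction of the area
series (the wall deflates once its integrity is lost).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from skimage import filters, measure

from .synthetic import Phantom, logistic_area

__all__ = [
    "AreaSeries",
    "SigmoidFit",
    "RuptureCall",
    "segment_area",
    "area_series",
    "fit_sigmoid",
    "detect_rupture",
]


@dataclass
class AreaSeries:
    """Projected follicle area against hours post-hCG."""

    times_h: np.ndarray
    areas_um2: np.ndarray
    follicle_id: int | None = None
    group: str | None = None
    treatment: str | None = None
    flags: np.ndarray | None = None  # True where segmentation was empty

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.areas_um2 = np.asarray(self.areas_um2, dtype=float)
        if len(self.times_h) != len(self.areas_um2):
            raise ValueError("times and areas must have equal length")
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.areas_um2 < 0):
            raise ValueError("areas must be non-negative")


@dataclass(frozen=True)
class SigmoidFit:
    a0: float
    amax: float
    k: float
    t50: float
    rmse: float
    peak_velocity_time: float  # = t50 for the logistic
    peak_area_time: float  # first time reaching 99% of the fitted plateau
    converged: bool = True
    message: str = ""


@dataclass(frozen=True)
class RuptureCall:
    ruptured: bool
    rupture_time_h: float | None
    max_drop_fraction: float

    def __post_init__(self) -> None:
        if self.ruptured != (self.rupture_time_h is not None):
            raise ValueError("rupture_time must be present iff ruptured")


def segment_area(frame: np.ndarray, pixel_size: float, method: str = "otsu",
                 threshold: float | None = None) -> tuple[float, bool]:
    """Projected area (um^2) of the largest bright object in one frame.

    The frame background is removed by subtracting the median of the
    two-pixel border ring (the follicle never touches the frame edge,
    so the ring is pure background even when the follicle fills most of
    the field), the residual is thresholded (Otsu, or a fixed value via
    ``method="fixed"``), and the pixel count of the largest connected
    foreground component is scaled by ``pixel_size**2``.

    Returns
    -------
    (area_um2, empty) : tuple
        ``empty=True`` flags frames with no usable foreground (area 0).
    """
    img = np.asarray(frame, dtype=float)
    border = np.concatenate([img[:2].ravel(), img[-2:].ravel(),
                             img[:, :2].ravel(), img[:, -2:].ravel()])
    img = img - np.median(border)
    np.clip(img, 0.0, None, out=img)
    if img.max() <= 0:
        return 0.0, True
    if method == "otsu":
        thr = filters.threshold_otsu(img)
    elif method == "fixed":
        if threshold is None:
            raise ValueError("method='fixed' requires a threshold")
        thr = threshold
    else:
        raise ValueError(f"unknown segmentation method {method!r}")
    fg = img > thr
    if not fg.any():
        return 0.0, True
    labels = measure.label(fg)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return float(counts.max() * pixel_size**2), False


def area_series(stack: np.ndarray | Phantom, pixel_size: float | None = None,
                interval_min: float | None = None, **segment_kwargs
                ) -> AreaSeries:
    """Measure the area series of a (T, H, W) stack.

    Accepts a raw stack (with explicit ``pixel_size`` and
    ``interval_min``) or a rendered time-lapse :class:`Phantom`, whose
    metadata supplies both.
    """
    meta: dict = {}
    if isinstance(stack, Phantom):
        ph = stack
        if ph.payload is None:
            raise ValueError("phantom has no rendered payload")
        pixel_size = ph.pixel_size if pixel_size is None else pixel_size
        interval_min = (ph.truth.get("interval_min", 10.0)
                        if interval_min is None else interval_min)
        meta = {k: ph.truth.get(k) for k in ("follicle_id", "group", "treatment")}
        stack = ph.payload
    if pixel_size is None or interval_min is None:
        raise ValueError("pixel_size and interval_min are required for raw stacks")
    arr = np.asarray(stack)
    if arr.ndim != 3:
        raise ValueError("expected a (T, H, W) stack")
    if arr.shape[0] < 10:
        raise ValueError("need >= 10 frames")
    areas = np.empty(arr.shape[0])
    flags = np.zeros(arr.shape[0], dtype=bool)
    for i, frame in enumerate(arr):
        areas[i], flags[i] = segment_area(frame, pixel_size, **segment_kwargs)
    times = np.arange(arr.shape[0]) * interval_min / 60.0
    return AreaSeries(times_h=times, areas_um2=areas, flags=flags, **meta)


def fit_sigmoid(series: AreaSeries, rupture: RuptureCall | None = None
                ) -> SigmoidFit:
    """Fit the logistic expansion curve to an area series.

    When a rupture was called, the fit window ends at the rupture time
    (the post-rupture contraction is not part of the expansion model).
    Initialization is multi-start over plausible rates and inflection
    times; non-convergence yields a flagged result, not an exception.
    """
    t = series.times_h
    a = series.areas_um2
    if rupture is not None and rupture.ruptured:
        keep = t < rupture.rupture_time_h
        t, a = t[keep], a[keep]
    if len(t) < 10:
        return SigmoidFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                          np.nan, converged=False,
                          message="fewer than 10 points in the fit window")

    a_lo, a_hi = float(a.min()), float(a.max())
    span = max(a_hi - a_lo, 1.0)
    # crude inflection guess: time of half rise
    half_idx = int(np.argmin(np.abs(a - (a_lo + 0.5 * span))))
    t_half = float(t[half_idx])
    t_span = float(t[-1] - t[0])

    best = None
    for k0 in (0.4, 1.0, 2.5):
        for t0 in (t_half, t[0] + 0.3 * t_span, t[0] + 0.7 * t_span):
            try:
                popt, _ = curve_fit(
                    logistic_area, t, a,
                    p0=[a_lo, a_hi, k0, t0],
                    bounds=([0.0, 0.0, 1e-3, t[0] - 2 * t_span],
                            [np.inf, np.inf, 50.0, t[-1] + 2 * t_span]),
                    maxfev=5000)
            except RuntimeError:
                continue
            rss = float(np.sum((logistic_area(t, *popt) - a) ** 2))
            if best is None or rss < best[1]:
                best = (popt, rss)
    if best is None:
        return SigmoidFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                          np.nan, converged=False,
                          message="all starts failed to converge")
    (a0, amax, k, t50), rss = best
    if amax < a0:  # express as an increasing curve
        a0, amax, k = amax, a0, -k
    rmse = float(np.sqrt(rss / len(t)))
    # first time A(t) = 0.99*Amax (closed form on the fitted curve)
    f = (0.99 * amax - a0) / (amax - a0) if amax > a0 else np.nan
    peak_area_time = (t50 + np.log(f / (1.0 - f)) / k
                      if np.isfinite(f) and 0.0 < f < 1.0 else np.nan)
    return SigmoidFit(a0=float(a0), amax=float(amax), k=float(k),
                      t50=float(t50), rmse=rmse,
                      peak_velocity_time=float(t50),
                      peak_area_time=float(peak_area_time))


def detect_rupture(series: AreaSeries, drop_fraction: float = 0.10,
                   min_frames: int = 3) -> RuptureCall:
    """Call rupture from sustained post-peak contraction.

    The follicle is called ruptured iff the area falls below
    ``(1 - drop_fraction)`` times its running maximum for at least
    ``min_frames`` consecutive frames; the rupture time is the first
    frame of that run.
    """
    a = series.areas_um2
    if len(a) < 10:
        raise ValueError("need >= 10 points")
    runmax = np.maximum.accumulate(a)
    below = a < (1.0 - drop_fraction) * runmax
    with np.errstate(divide="ignore", invalid="ignore"):
        drops = np.where(runmax > 0, 1.0 - a / runmax, 0.0)
    max_drop = float(drops.max(initial=0.0))
    run = 0
    for i, b in enumerate(below):
        run = run + 1 if b else 0
        if run >= min_frames:
            start = i - min_frames + 1
            return RuptureCall(ruptured=True,
                               rupture_time_h=float(series.times_h[start]),
                               max_drop_fraction=max_drop)
    return RuptureCall(ruptured=False, rupture_time_h=None,
                       max_drop_fraction=max_drop)
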
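"""Cavity-pressure estimation from oil-media interface curvature.

The micropipette pressure sensor holds an oil column against the medium
(or against follicular fluid once inserted). At equilibrium the
Young-Laplace relation links the transducer gauge pressure ``Pg``, the
spherical-cap interface radius ``R`` and the pressure on the far side:
``Pg - 2*gamma/R = P_far``. Calibrating in open medium (``P_far = 0``)
gives the surface tension ``gamma`` as the slope of ``Pg`` against the
curvature ``2/R``; differencing the before/after-insertion states gives
the cavity gauge pressure

    P = (Pg_in - Pg_out) - 2*gamma*(1/R_in - 1/R_out).

Radii come from least-squares circle fits to the imaged meniscus arc.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from skimage import measure

from .units import MMHG_TO_PA
from .synthetic import Phantom

__all__ = [
    "CircleFit",
    "InterfaceObservation",
    "CalibrationFit",
    "CavityPressure",
    "DegenerateFitError",
    "EdgeDetectionError",
    "fit_circle",
    "calibrate_surface_tension",
    "compute_cavity_pressure",
    "pressure_cohort",
]


class DegenerateFitError(ValueError):
    """Circle fit is underdetermined (collinear or coincident points)."""


class EdgeDetectionError(ValueError):
    """Too few meniscus edge pixels were found in the image."""


@dataclass(frozen=True)
class CircleFit:
    center_um: tuple[float, float]  # (row, col)
    radius_um: float
    residual_px: float  # RMS radial residual, pixels
    n_points: int


@dataclass(frozen=True)
class InterfaceObservation:
    """One phase of a pressure measurement: gauge reading + fitted radius."""

    phase: str  # {"before_insertion", "after_insertion"}
    gauge_pressure_pa: float
    radius_um: float
    fit_residual_px: float = 0.0

    def __post_init__(self) -> None:
        if self.phase not in ("before_insertion", "after_insertion"):
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.radius_um <= 0:
            raise ValueError("radius_of_curvature must be positive")


@dataclass(frozen=True)
class CalibrationFit:
    """Surface tension and chamber offset from a calibration series."""

    surface_tension: float  # N/m (slope of Pg against 2/R)
    pressure_offset: float  # Pa (intercept)
    r_squared: float
    n_points: int
    valid: bool = True


@dataclass(frozen=True)
class CavityPressure:
    value_mmhg: float
    value_pa: float
    components: tuple[float, float]  # (delta gauge Pa, curvature term Pa)


def _extract_arc_points(image: np.ndarray, border_margin: int = 2
                        ) -> np.ndarray:
    """Subpixel meniscus boundary points from a rendered/acquired snapshot.

    Takes the longest mid-level isocontour of the (bright-phase) image
    and discards vertices that hug the frame border, leaving the free
    arc. Returns (N, 2) points in pixel units (row, col).
    """
    img = np.asarray(image, dtype=float)
    lo, hi = float(img.min()), float(img.max())
    if hi - lo <= 1e-12:
        raise EdgeDetectionError("image has no contrast")
    level = 0.5 * (lo + hi)
    contours = measure.find_contours(img, level)
    if not contours:
        raise EdgeDetectionError("no isocontour found at the mid level")
    contour = max(contours, key=len)
    h, w = img.shape
    keep = ((contour[:, 0] > border_margin) & (contour[:, 0] < h - 1 - border_margin)
            & (contour[:, 1] > border_margin) & (contour[:, 1] < w - 1 - border_margin))
    pts = contour[keep]
    if len(pts) < 8:
        raise EdgeDetectionError(
            f"only {len(pts)} arc pixels after border trimming; need >= 8")
    return pts


def _kasa_circle(pts: np.ndarray) -> tuple[float, float, float]:
    """Kasa algebraic circle fit; exact on noiseless circles and a good
    starting point for the geometric refinement."""
    y = pts[:, 0] - pts[:, 0].mean()
    x = pts[:, 1] - pts[:, 1].mean()
    design = np.column_stack([2.0 * y, 2.0 * x, np.ones_like(x)])
    target = x * x + y * y
    sol, _, rank, sv = np.linalg.lstsq(design, target, rcond=None)
    if rank < 3 or sv[-1] < 1e-10 * max(sv[0], 1.0):
        raise DegenerateFitError("points are collinear or coincident")
    cy, cx, c = sol
    r2 = c + cy * cy + cx * cx
    if r2 <= 0:
        raise DegenerateFitError("degenerate circle fit (non-positive radius)")
    return cy + pts[:, 0].mean(), cx + pts[:, 1].mean(), float(np.sqrt(r2))


def fit_circle(points_or_image: np.ndarray, pixel_size: float = 1.0
               ) -> CircleFit:
    """Least-squares circle through arc points or an interface image.

    Parameters
    ----------
    points_or_image : ndarray
        Either an (N, 2) array of (row, col) arc points in pixel units,
        or a 2D grayscale snapshot from which the meniscus boundary is
        extracted as the longest mid-level isocontour away from the
        frame border.
    pixel_size : float
        um per pixel; fitted centre/radius are reported in um.

    Returns
    -------
    CircleFit
        Geometric (radial-residual) least-squares circle, refined from a
        Taubin algebraic fit; exact on noiseless circles.
    """
    arr = np.asarray(points_or_image, dtype=float)
    if arr.ndim == 2 and arr.shape[1] == 2 and arr.shape[0] >= 3:
        pts = arr
    elif arr.ndim == 2:
        pts = _extract_arc_points(arr)
    else:
        raise ValueError("expected an (N,2) point array or a 2D image")
    if len(pts) < 3:
        raise DegenerateFitError("need at least 3 points to fit a circle")

    cy0, cx0, r0 = _kasa_circle(pts)

    def radial_residuals(params: np.ndarray) -> np.ndarray:
        cy, cx = params
        d = np.hypot(pts[:, 0] - cy, pts[:, 1] - cx)
        return d - d.mean()

    sol = optimize.least_squares(radial_residuals, x0=[cy0, cx0], method="lm")
    cy, cx = sol.x
    dist = np.hypot(pts[:, 0] - cy, pts[:, 1] - cx)
    radius = float(dist.mean())
    resid = float(np.sqrt(np.mean((dist - radius) ** 2)))
    span = np.ptp(pts, axis=0).max() + 1.0
    if radius > 1e6 * span:
        raise DegenerateFitError("points are effectively collinear")
    return CircleFit(center_um=(cy * pixel_size, cx * pixel_size),
                     radius_um=radius * pixel_size,
                     residual_px=resid, n_points=len(pts))


def calibrate_surface_tension(pairs: pd.DataFrame | np.ndarray,
                              cap_factor: float = 2.0) -> CalibrationFit:
    """Estimate surface tension from (gauge pressure, radius) pairs.

    Ordinary least squares of gauge pressure (Pa) against interface
    curvature ``cap_factor / R`` (1/m): the slope is the surface tension
    in N/m, the intercept the chamber pressure offset. ``cap_factor=2``
    is the spherical-cap Young-Laplace convention; a cylindrical
    interface would use 1.

    Accepts a DataFrame with columns ``gauge_pressure_pa, radius_um`` or
    an (N, 2) array in that order.
    """
    if isinstance(pairs, pd.DataFrame):
        gauge = pairs["gauge_pressure_pa"].to_numpy(float)
        radius = pairs["radius_um"].to_numpy(float)
    else:
        arr = np.asarray(pairs, dtype=float)
        gauge, radius = arr[:, 0], arr[:, 1]
    if len(gauge) < 3:
        raise ValueError("need >= 3 calibration pairs")
    if np.any(radius <= 0):
        raise ValueError("radii must be positive")
    x = cap_factor / (radius * 1e-6)  # curvature, 1/m
    if np.ptp(x) < 1e-9 * max(abs(x).max(), 1.0):
        raise DegenerateFitError("calibration pairs share one curvature")
    design = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), *_ = np.linalg.lstsq(design, gauge, rcond=None)
    fitted = design @ [slope, intercept]
    ss_res = float(np.sum((gauge - fitted) ** 2))
    ss_tot = float(np.sum((gauge - gauge.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    valid = slope > 0
    if not valid:
        warnings.warn("calibration slope is non-positive: non-physical "
                      "surface tension; fit flagged invalid", stacklevel=2)
    return CalibrationFit(surface_tension=float(slope),
                          pressure_offset=float(intercept),
                          r_squared=float(r2), n_points=len(gauge),
                          valid=bool(valid))


def compute_cavity_pressure(cal: CalibrationFit, before: InterfaceObservation,
                            after: InterfaceObservation) -> CavityPressure:
    """Cavity gauge pressure from a before/after interface pair.

    ``P = (Pg_in - Pg_out) - 2*gamma*(1/R_in - 1/R_out)`` with radii in
    metres; reported both in Pa and mmHg.
    """
    if before.phase != "before_insertion" or after.phase != "after_insertion":
        raise ValueError("expected observations in (before_insertion, "
                         "after_insertion) order")
    if not cal.valid:
        raise ValueError("calibration fit is flagged invalid")
    gamma = cal.surface_tension
    delta_gauge = after.gauge_pressure_pa - before.gauge_pressure_pa
    curvature_term = 2.0 * gamma * (1.0 / (after.radius_um * 1e-6)
                                    - 1.0 / (before.radius_um * 1e-6))
    p_pa = delta_gauge - curvature_term
    return CavityPressure(value_mmhg=p_pa / MMHG_TO_PA, value_pa=p_pa,
                          components=(delta_gauge, curvature_term))


def pressure_cohort(phantoms: list[dict], cal: CalibrationFit) -> pd.DataFrame:
    """Run the full image -> circle fit -> Young-Laplace chain on a cohort.

    Each entry must carry an ``"interface"`` (before, after) Phantom
    pair (as produced by :func:`follimech.synthetic.simulate_cohort`).
    Failures are flagged per record (``ok=False`` with a reason), never
    silently dropped.
    """
    rows = []
    for entry in phantoms:
        fid = entry.get("follicle_id")
        row: dict = {"follicle_id": fid, "ok": True, "error": ""}
        try:
            pair = entry["interface"]
        except KeyError:
            row.update(ok=False, error="missing interface phase pair")
            rows.append(row)
            continue
        before_ph, after_ph = pair
        for key in ("group", "timepoint_h", "treatment"):
            row[key] = before_ph.truth.get(key)
        try:
            obs = []
            for ph in (before_ph, after_ph):
                fit = fit_circle(ph.payload, ph.pixel_size)
                obs.append(InterfaceObservation(
                    phase=ph.truth["phase"],
                    gauge_pressure_pa=ph.truth["gauge_pressure_pa"],
                    radius_um=fit.radius_um,
                    fit_residual_px=fit.residual_px))
            cp = compute_cavity_pressure(cal, obs[0], obs[1])
            row.update(pressure_mmhg=cp.value_mmhg, pressure_pa=cp.value_pa,
                       radius_before_um=obs[0].radius_um,
                       radius_after_um=obs[1].radius_um)
        except (ValueError, KeyError) as exc:
            row.update(ok=False, error=str(exc), pressure_mmhg=np.nan,
                       pressure_pa=np.nan)
        rows.append(row)
    return pd.DataFrame.from_records(rows)
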
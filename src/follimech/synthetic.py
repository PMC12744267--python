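"""Synthetic phantoms with known ground truth.

Every input the analysis pipeline consumes can be generated here:
circular-arc oil-media interface snapshots (micropipette pressure
sensing), calibration tables of gauge pressure against interface radius,
brightfield-like time-lapse stacks of an expanding follicle, OCT-like
intensity volumes of a fluid-filled follicle with an asymmetric cellular
wall and a cumulus-oocyte complex (COC), and whole cohorts built from
the presets in :mod:`follimech.presets`.

Each phantom carries its ground truth so downstream estimators can be
validated by render-then-measure round trips.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .presets import GeneratorPreset, make_preset
from .units import MMHG_TO_PA

__all__ = [
    "Phantom",
    "ParameterError",
    "simulate_interface_pair",
    "simulate_calibration_set",
    "simulate_timelapse",
    "simulate_oct_volume",
    "simulate_cohort",
]


class ParameterError(ValueError):
    """Physically or numerically inadmissible generator parameters."""


@dataclass
class Phantom:
    """A synthetic image/volume plus its ground truth.

    ``payload`` is a 2D image, a (T, H, W) stack, a (Z, Y, X) volume, or
    ``None`` for series-level phantoms that skip rendering. ``truth``
    holds the exact geometry/physics used to generate it.
    """

    payload: np.ndarray | None
    pixel_size: float  # um per pixel (isotropic)
    truth: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be positive")
        if self.payload is not None and not np.all(np.isfinite(self.payload)):
            raise ParameterError("payload intensities must be finite")


def _smoothstep(x: np.ndarray) -> np.ndarray:
    """Logistic edge profile; ~0/1 within a few units of the boundary."""
    return 1.0 / (1.0 + np.exp(-np.clip(x, -40.0, 40.0)))


# ---------------------------------------------------------------------------
# Interface snapshots (pressure sensing)
# ---------------------------------------------------------------------------

def _render_arc(radius_um: float, pixel_size: float, noise_sd: float,
                rng: np.random.Generator, edge_width_px: float = 0.7
                ) -> tuple[np.ndarray, tuple[float, float]]:
    """Render a one-sided meniscus bounded by a circular arc.

    The circle centre sits half a radius off the left image edge, so the
    bright oil phase occupies the left part of the frame and its
    boundary is an arc spanning 120 degrees. ``noise_sd`` is the
    implied edge-localization error in pixels: additive Gaussian
    intensity noise is applied with standard deviation
    ``noise_sd / (4 * edge_width_px)``, the level at which the
    mid-level boundary crossing wanders by ~``noise_sd`` pixels
    (the edge gradient of the logistic profile is 1/(4w)).

    Returns the image and the circle centre in um (row, col convention,
    origin at pixel (0, 0) centre).
    """
    r_px = radius_um / pixel_size
    if r_px <= 5:
        raise ParameterError(
            f"interface radius {radius_um:.3g} um is below 5 pixels at "
            f"{pixel_size:g} um/px; rendering would be unresolvable"
        )
    # centre at col = -r/2 -> visible arc half-angle 60 deg each side
    height = int(np.ceil(2 * r_px * np.sin(np.pi / 3))) + 12
    width = int(np.ceil(r_px / 2)) + 10
    cy = (height - 1) / 2.0
    cx = -r_px / 2.0
    yy, xx = np.mgrid[0:height, 0:width]
    dy = yy - cy
    dx = xx - cx
    rho = np.hypot(dy, dx)
    img = _smoothstep((r_px - rho) / edge_width_px)
    if noise_sd > 0:
        sd_intensity = noise_sd / (4.0 * edge_width_px)
        img = img + rng.normal(0.0, sd_intensity, size=img.shape)
    return img.astype(np.float64), (cy * pixel_size, cx * pixel_size)


def simulate_interface_pair(true_pressure: float, surface_tension: float = 0.030,
                            gauge_out: float = 1000.0, noise_sd: float = 0.5,
                            seed: int | np.random.Generator = 0,
                            pixel_size: float = 2.0,
                            ) -> tuple[Phantom, Phantom]:
    """Render the before/after-insertion interface images of one follicle.

    Parameters
    ----------
    true_pressure : float
        Ground-truth cavity gauge pressure, mmHg.
    surface_tension : float
        Oil-media surface tension gamma, N/m.
    gauge_out : float
        Transducer gauge pressure before insertion, Pa. The implied
        interface radius is ``R_out = 2*gamma/gauge_out``.
    noise_sd : float
        Radial boundary jitter of the rendered arc, pixels.
    seed : int or Generator
        Randomness for the jitter and the after-insertion gauge setting.
    pixel_size : float
        um per pixel of the rendered snapshots.

    Returns
    -------
    (before, after) : tuple of Phantom
        Truths store phase, gauge pressure (Pa), the exact interface
        radius (um) and the true cavity pressure.
    """
    if surface_tension <= 0:
        raise ParameterError("surface_tension must be positive")
    rng = np.random.default_rng(seed)
    p_pa = true_pressure * MMHG_TO_PA
    if gauge_out <= 0:
        raise ParameterError("gauge_out must be positive (implied radius)")
    r_out_um = 2.0 * surface_tension / gauge_out * 1e6
    # the operator re-equilibrates the pump after insertion; the setting
    # lands near gauge_out + P with ~10% chamber variability
    gauge_in = gauge_out * (1.0 + rng.uniform(-0.10, 0.10)) + p_pa
    if gauge_in - p_pa <= 0:
        raise ParameterError("after-insertion interface radius is non-positive")
    r_in_um = 2.0 * surface_tension / (gauge_in - p_pa) * 1e6

    phantoms = []
    for phase, gauge, radius in (("before_insertion", gauge_out, r_out_um),
                                 ("after_insertion", gauge_in, r_in_um)):
        img, center_um = _render_arc(radius, pixel_size, noise_sd, rng)
        phantoms.append(Phantom(
            payload=img,
            pixel_size=pixel_size,
            truth={
                "phase": phase,
                "gauge_pressure_pa": float(gauge),
                "radius_um": float(radius),
                "center_um": center_um,
                "true_pressure_mmhg": float(true_pressure),
                "surface_tension": float(surface_tension),
            },
        ))
    return phantoms[0], phantoms[1]


def simulate_calibration_set(surface_tension: float = 0.030, offset: float = 100.0,
                             n_levels: int = 8, noise_sd: float = 10.0,
                             seed: int | np.random.Generator = 0,
                             radius_range_um: tuple[float, float] = (40.0, 100.0),
                             ) -> pd.DataFrame:
    """Generate a calibration table of (gauge pressure, interface radius).

    Rows satisfy ``gauge = offset + 2*gamma/R + noise`` with ``R`` spread
    over ``radius_range_um``; this is the synthetic analogue of stepping
    a syringe pump through pressure levels and imaging the meniscus.

    Returns a DataFrame with columns ``gauge_pressure_pa`` and
    ``radius_um``.
    """
    if n_levels < 3:
        raise ParameterError("n_levels must be >= 3 (regression underdetermined)")
    if surface_tension <= 0:
        raise ParameterError("surface_tension must be positive")
    rng = np.random.default_rng(seed)
    radii = np.linspace(radius_range_um[0], radius_range_um[1], n_levels)
    gauges = offset + 2.0 * surface_tension / (radii * 1e-6)
    if noise_sd > 0:
        gauges = gauges + rng.normal(0.0, noise_sd, size=n_levels)
    return pd.DataFrame({"gauge_pressure_pa": gauges, "radius_um": radii})


# ---------------------------------------------------------------------------
# Time-lapse stacks (expansion / rupture)
# ---------------------------------------------------------------------------

def logistic_area(t: np.ndarray, a0: float, amax: float, k: float,
                  t50: float) -> np.ndarray:
    """Logistic follicle-expansion curve A(t), um^2."""
    return a0 + (amax - a0) / (1.0 + np.exp(-k * (np.asarray(t, float) - t50)))


def simulate_timelapse(preset: GeneratorPreset, n_frames: int = 96,
                       interval_min: float = 10.0,
                       seed: int | np.random.Generator = 0,
                       pixel_size: float = 4.0, noise_sd_area: float = 2e3,
                       render: bool = True,
                       ruptured: bool | None = None,
                       sigmoid_params: Sequence[float] | None = None,
                       ) -> Phantom:
    """Simulate one follicle's expansion recording.

    The follicle projects as a bright disk whose area follows a logistic
    curve; with probability ``preset.rupture_prob`` (or as forced by
    ``ruptured``) a rupture time is drawn after the inflection, after
    which the wall contracts and the area decays monotonically toward a
    deflated plateau. Area noise is additive Gaussian, applied at the
    series level and propagated into the rendered disk radii.

    With ``render=False`` the payload is omitted and only the truth
    (including the noisy measured-area series) is produced, which is
    sufficient for rupture-call and curve-fitting studies.
    """
    if n_frames < 10:
        raise ParameterError("n_frames must be >= 10")
    rng = np.random.default_rng(seed)
    if sigmoid_params is None:
        a0, amax, k, t50 = _draw_sigmoid_params(preset, rng)
    else:
        a0, amax, k, t50 = map(float, sigmoid_params)
    times = np.arange(n_frames) * interval_min / 60.0  # hours post-hCG

    if ruptured is None:
        ruptured = bool(rng.random() < preset.rupture_prob)
    rupture_time = float(t50 + rng.uniform(1.0, 5.0)) if ruptured else None

    area_clean = logistic_area(times, a0, amax, k, t50)
    if ruptured:
        post = times >= rupture_time
        a_r = logistic_area(np.array([rupture_time]), a0, amax, k, t50)[0]
        deflate, tau = 0.55, 1.5  # residual fraction, decay constant (h)
        area_clean = np.where(
            post,
            a_r * (deflate + (1 - deflate) * np.exp(-(times - rupture_time) / tau)),
            area_clean,
        )
    noise = rng.normal(0.0, noise_sd_area, size=n_frames) if noise_sd_area > 0 else 0.0
    area_noisy = np.maximum(area_clean + noise, 1.0)

    payload = None
    if render:
        radii_px = np.sqrt(area_noisy / np.pi) / pixel_size
        half = int(np.ceil(radii_px.max())) + 6
        n = 2 * half + 1
        yy, xx = np.mgrid[0:n, 0:n]
        rho = np.hypot(yy - half, xx - half)
        payload = _smoothstep(
            (radii_px[:, None, None] - rho[None, :, :]) / 0.8
        ).astype(np.float32)
        if noise_sd_area > 0:
            payload = payload + rng.normal(0.0, 0.02, size=payload.shape
                                           ).astype(np.float32)

    return Phantom(
        payload=payload,
        pixel_size=pixel_size,
        truth={
            "times_h": times,
            "area_true_um2": area_clean,
            "area_series_um2": area_noisy,
            "sigmoid_params": (a0, amax, k, t50),
            "ruptured": bool(ruptured),
            "rupture_time_h": rupture_time,
            "interval_min": float(interval_min),
            "group": preset.group,
            "timepoint_h": preset.timepoint_h,
            "treatment": preset.treatment,
        },
    )


def _draw_sigmoid_params(preset: GeneratorPreset, rng: np.random.Generator
                         ) -> tuple[float, float, float, float]:
    """Per-follicle expansion-curve parameters around the preset values."""
    a0, amax, k, t50 = preset.sigmoid_params
    a0 = a0 * (1.0 + 0.05 * rng.standard_normal())
    amax = max(amax * (1.0 + 0.08 * rng.standard_normal()), a0 * 1.05)
    k = max(k * (1.0 + 0.10 * rng.standard_normal()), 0.3)
    t50 = t50 + 0.5 * rng.standard_normal()
    return a0, amax, k, t50


# ---------------------------------------------------------------------------
# OCT-like volumes (wall / antrum / COC)
# ---------------------------------------------------------------------------

_OCT_LEVELS = {"background": 0.08, "antrum": 0.08, "coc": 0.50, "wall": 1.00}


def _thickness_scale(t_mean: float, asym: float, r_out: float) -> float:
    """Scale factor c so the area-weighted midplane mean thickness of a
    shell with azimuthal profile ``c*t_mean*(1 + asym*cos(phi))`` equals
    ``t_mean``.

    Pixel-count weighting over the midplane annulus weights angle phi by
    t(phi) * r_mid(phi), so the weighted mean exceeds the plain angular
    mean wherever asym > 0; c compensates (c <= 1).
    """
    if asym == 0:
        return 1.0
    phi = np.linspace(0.0, 2.0 * np.pi, 4096, endpoint=False)
    f = 1.0 + asym * np.cos(phi)

    def weighted_mean(c: float) -> float:
        t = c * t_mean * f
        r_mid = r_out - t / 2.0
        return float(np.sum(t * t * r_mid) / np.sum(t * r_mid))

    return brentq(lambda c: weighted_mean(c) - t_mean, 0.2, 1.5, xtol=1e-12)


def simulate_oct_volume(preset: GeneratorPreset,
                        grid_shape: tuple[int, int, int] | None = None,
                        voxel_size: float = 3.0,
                        seed: int | np.random.Generator = 0,
                        speckle_looks: float = 16.0,
                        radius_um: float | None = None,
                        thickness_mean_um: float | None = None,
                        with_coc: bool = True,
                        ) -> Phantom:
    """Render an OCT-like intensity volume of one antral follicle.

    Geometry: a spherical outer surface of radius ``r_out`` whose wall
    thickness varies with azimuth, ``t(phi) = c * t_mean *
    (1 + a*cos(phi - phi0))``, rescaled (factor ``c``) so that the
    pixel-count-weighted mean thickness over the equatorial midplane
    equals ``thickness_mean_um``. Interior fluid (antrum) is dark, the
    wall is bright, and a COC blob of intermediate intensity floats in
    the antrum without touching the wall. Noise is multiplicative
    gamma-distributed speckle with ``speckle_looks`` looks (cv =
    1/sqrt(looks)); set ``speckle_looks=inf`` (or <=0) for a noiseless
    phantom.

    Truth stores exact wall/antrum/COC masks, the analytic thickness
    profile, and the midplane-slice index.
    """
    rng = np.random.default_rng(seed)
    r_out = float(radius_um if radius_um is not None else preset.follicle_radius_mean)
    t_mean = float(thickness_mean_um if thickness_mean_um is not None
                   else preset.wall_thickness_mean)
    asym = preset.thickness_asymmetry
    if t_mean * (1 + asym) >= r_out:
        raise ParameterError("wall thickness exceeds follicle radius (shell "
                             "self-intersection)")
    c = _thickness_scale(t_mean, asym, r_out)
    if c * t_mean * (1 + asym) >= r_out:
        raise ParameterError("rescaled wall thickness exceeds follicle radius")
    phi0 = float(rng.uniform(0.0, 2.0 * np.pi))

    if grid_shape is None:
        half = int(np.ceil((r_out + 5 * voxel_size) / voxel_size))
        grid_shape = (2 * half + 1,) * 3
    nz, ny, nx = grid_shape
    if min(grid_shape) * voxel_size < 2 * r_out:
        raise ParameterError("grid does not accommodate the follicle radius")
    cz, cy, cx = ((n - 1) / 2.0 for n in grid_shape)
    z = (np.arange(nz) - cz)[:, None, None] * voxel_size
    y = (np.arange(ny) - cy)[None, :, None] * voxel_size
    x = (np.arange(nx) - cx)[None, None, :] * voxel_size
    rho = np.sqrt(z * z + y * y + x * x)
    phi = np.arctan2(y, x)  # azimuth in the (x, y) plane; broadcast (1,ny,nx)
    t_phi = c * t_mean * (1.0 + asym * np.cos(phi - phi0))
    r_in = r_out - t_phi

    w = 0.7 * voxel_size  # edge smoothing
    inside_out = _smoothstep((r_out - rho) / w)
    inside_in = _smoothstep((r_in - rho) / w)
    lv = _OCT_LEVELS
    vol = (lv["background"]
           + (lv["wall"] - lv["background"]) * (inside_out - inside_in)
           + (lv["antrum"] - lv["background"]) * inside_in)

    coc_mask = np.zeros(grid_shape, dtype=bool)
    coc_center = coc_radius = None
    r_in_min = r_out - c * t_mean * (1 + asym)
    if with_coc:
        coc_radius = 0.30 * r_in_min
        d = 0.40 * r_in_min
        ang = rng.uniform(0.0, 2.0 * np.pi)
        coc_center = (0.0, d * np.sin(ang), d * np.cos(ang))  # (z, y, x) um
        d_coc = np.sqrt((z - coc_center[0]) ** 2 + (y - coc_center[1]) ** 2
                        + (x - coc_center[2]) ** 2)
        coc_frac = _smoothstep((coc_radius - d_coc) / w)
        vol = vol + (lv["coc"] - lv["antrum"]) * coc_frac
        coc_mask = d_coc <= coc_radius

    if speckle_looks and np.isfinite(speckle_looks) and speckle_looks > 0:
        vol = vol * rng.gamma(speckle_looks, 1.0 / speckle_looks, size=vol.shape)

    wall_mask = (rho <= r_out) & (rho > r_in)
    antrum_mask = (rho <= r_in) & ~coc_mask
    midplane_z = int(round(cz))

    return Phantom(
        payload=vol.astype(np.float32),
        pixel_size=voxel_size,
        truth={
            "radius_um": r_out,
            "thickness_mean_um": t_mean,
            "thickness_scale": c,
            "thickness_asymmetry": asym,
            "phi0": phi0,
            "wall_mask": wall_mask,
            "antrum_mask": antrum_mask,
            "coc_mask": coc_mask,
            "coc_center_um": coc_center,
            "coc_radius_um": coc_radius,
            "midplane_z": midplane_z,
            "antrum_wall_ratio": float(antrum_mask.sum() / wall_mask.sum()),
            "group": preset.group,
            "timepoint_h": preset.timepoint_h,
            "treatment": preset.treatment,
        },
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def simulate_cohort(design: pd.DataFrame | Sequence[tuple[GeneratorPreset, int]],
                    seed: int = 0,
                    modalities: Sequence[str] = ("interface",),
                    **modality_kwargs: dict,
                    ) -> tuple[list[dict], pd.DataFrame]:
    """Generate a cohort of phantom follicles with a ground-truth table.

    Parameters
    ----------
    design : DataFrame or sequence
        Either rows with columns ``group, timepoint_h, treatment,
        n_follicles`` (presets are built via :func:`make_preset`) or a
        sequence of ``(preset, n_follicles)`` pairs.
    seed : int
        Master seed; per-follicle streams are spawned from it, so the
        truth table and payloads are reproducible bit for bit.
    modalities : subset of {"interface", "timelapse", "oct"}
        Which phantom kinds to generate per follicle.
    **modality_kwargs
        Keyword overrides per modality, e.g.
        ``interface={"noise_sd": 0.0}``, ``timelapse={"render": False}``,
        ``oct={"voxel_size": 4.0}``.

    Returns
    -------
    phantoms : list of dict
        One entry per follicle: ``follicle_id`` plus one key per
        requested modality ("interface" maps to a (before, after) pair).
    truth : DataFrame
        One row per follicle with the drawn ground-truth quantities.
    """
    if isinstance(design, pd.DataFrame):
        if len(design) == 0:
            raise ParameterError("empty cohort design")
        rows = [
            (make_preset(r.group, int(r.timepoint_h), r.treatment),
             int(r.n_follicles))
            for r in design.itertuples()
        ]
    else:
        rows = [(p, int(n)) for p, n in design]
        if not rows:
            raise ParameterError("empty cohort design")
    if any(n < 1 for _, n in rows):
        raise ParameterError("n_follicles must be >= 1 in every design row")
    unknown = set(modalities) - {"interface", "timelapse", "oct"}
    if unknown:
        raise ParameterError(f"unknown modalities: {sorted(unknown)}")

    ss = np.random.SeedSequence(seed)
    phantoms: list[dict] = []
    records: list[dict] = []
    fid = 0
    for preset, n in rows:
        for _ in range(n):
            child = ss.spawn(1)[0]
            rng = np.random.default_rng(child)
            pressure = float(rng.normal(preset.pressure_mean, preset.pressure_sd))
            thickness = float(np.clip(
                rng.normal(preset.wall_thickness_mean,
                           0.05 * preset.wall_thickness_mean),
                5.0, 0.8 * preset.follicle_radius_mean))
            radius = float(max(
                rng.normal(preset.follicle_radius_mean,
                           0.05 * preset.follicle_radius_mean),
                1.5 * thickness / (1 - preset.thickness_asymmetry)))
            ruptured = bool(rng.random() < preset.rupture_prob)
            entry: dict[str, Any] = {"follicle_id": fid}
            if "interface" in modalities:
                kw = dict(modality_kwargs.get("interface", {}))
                before, after = simulate_interface_pair(
                    pressure, seed=rng, **kw)
                for ph in (before, after):
                    ph.truth.update(follicle_id=fid, group=preset.group,
                                    timepoint_h=preset.timepoint_h,
                                    treatment=preset.treatment)
                entry["interface"] = (before, after)
            if "timelapse" in modalities:
                kw = dict(modality_kwargs.get("timelapse", {}))
                ph = simulate_timelapse(preset, seed=rng, ruptured=ruptured, **kw)
                ph.truth["follicle_id"] = fid
                entry["timelapse"] = ph
            if "oct" in modalities:
                kw = dict(modality_kwargs.get("oct", {}))
                ph = simulate_oct_volume(preset, seed=rng, radius_um=radius,
                                         thickness_mean_um=thickness, **kw)
                ph.truth["follicle_id"] = fid
                entry["oct"] = ph
            phantoms.append(entry)
            records.append({
                "follicle_id": fid,
                "group": preset.group,
                "timepoint_h": preset.timepoint_h,
                "treatment": preset.treatment,
                "pressure_true_mmhg": pressure,
                "thickness_true_um": thickness,
                "radius_true_um": radius,
                "ruptured_true": ruptured,
            })
            fid += 1
    return phantoms, pd.DataFrame.from_records(records)
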
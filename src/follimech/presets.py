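"""Cohort presets for the synthetic-data generators.

Each preset bundles the ground-truth physics and geometry of one
experimental cell (age group x hours post-hCG x treatment): the
intrafollicular pressure distribution, the area-weighted wall-thickness
target, the logistic expansion-curve parameters, and the rupture
probability. Anchored quantities come from the murine ex vivo ovulation
cohorts the package emulates:

* young-control cavity pressure at 0 h: 1.36 +/- 0.66 mmHg; aged: 2.88
  +/- 2.36 mmHg, flat across the ovulatory window.
* young-control area-weighted wall thickness 63.1 / 65.6 / 50.9 /
  44.4 um at 0 / 4 / 8 / 11 h post-hCG.
* rupture incidence 80% in controls vs 3% under 1 mM 4-MU (a hyaluronan-
  synthesis inhibitor), with an intermediate dose in between.

Quantities the source cohorts do not pin down numerically (pressures at
4-11 h, 0.5 mM rupture rate, expansion-curve amplitudes) carry defaults
chosen to satisfy the qualitative orderings documented in
docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

GROUPS = ("young", "old")
TIMEPOINTS_H = (0, 4, 8, 11)
TREATMENTS = ("control", "mu_0.5mM", "mu_1mM")


class PresetError(ValueError):
    """Unknown group / timepoint / treatment combination."""


@dataclass(frozen=True)
class GeneratorPreset:
    """Ground-truth parameters for one cohort cell.

    Attributes
    ----------
    group : {"young", "old"}
        Reproductive-age group.
    timepoint_h : int
        Hours post-hCG (0, 4, 8 or 11).
    treatment : {"control", "mu_0.5mM", "mu_1mM"}
        4-MU dose arm.
    pressure_mean, pressure_sd : float
        Intrafollicular gauge pressure distribution, mmHg.
    wall_thickness_mean : float
        Target area-weighted mean wall thickness at the midplane, um.
    thickness_asymmetry : float
        Relative amplitude of the azimuthal thickness modulation, in
        [0, 1).
    follicle_radius_mean : float
        Outer equivalent radius of the follicle, um.
    antrum_ratio_mean : float
        Antrum/wall volume ratio implied by the shell geometry
        (radius and thickness); informational.
    sigmoid_params : tuple
        (A0, Amax, k, t50): baseline area um^2, plateau area um^2,
        logistic rate 1/h, inflection time h.
    rupture_prob : float
        Probability that the follicle ruptures during the recording.
    seed : int
        Default seed; generators accept an explicit override.
    """

    group: str
    timepoint_h: int
    treatment: str
    pressure_mean: float
    pressure_sd: float
    wall_thickness_mean: float
    thickness_asymmetry: float
    follicle_radius_mean: float
    antrum_ratio_mean: float
    sigmoid_params: tuple[float, float, float, float]
    rupture_prob: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pressure_sd < 0:
            raise PresetError("pressure_sd must be >= 0")
        if not 0 < self.wall_thickness_mean < self.follicle_radius_mean:
            raise PresetError(
                "wall thickness must be positive and below the follicle radius"
            )
        if not 0.0 <= self.rupture_prob <= 1.0:
            raise PresetError("rupture_prob must lie in [0, 1]")
        if not 0.0 <= self.thickness_asymmetry < 1.0:
            raise PresetError("thickness_asymmetry must lie in [0, 1)")
        if self.antrum_ratio_mean <= 0:
            raise PresetError("antrum_ratio_mean must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sigmoid_params"] = list(self.sigmoid_params)
        return d


def _shell_antrum_ratio(radius: float, thickness: float) -> float:
    """Antrum/wall volume ratio of a concentric spherical shell."""
    r_in = radius - thickness
    return r_in**3 / (radius**3 - r_in**3)


# Young-control wall thickness per timepoint (um, area-weighted means).
_THICKNESS_BY_TP = {0: 63.1, 4: 65.6, 8: 50.9, 11: 44.4}

# Outer follicle radius per timepoint (um): antral expansion 0 -> 11 h.
_RADIUS_BY_TP = {0: 180.0, 4: 200.0, 8: 230.0, 11: 250.0}

# Young-control pressure (mean, sd) in mmHg: rises 0 -> 4 h, stays
# elevated through 11 h. Only the 0 h value is numerically anchored.
_YOUNG_PRESSURE = {0: (1.36, 0.66), 4: (3.0, 1.0), 8: (3.0, 1.0), 11: (3.0, 1.0)}

# Aged follicles: elevated baseline, no ovulatory rise.
_OLD_PRESSURE = {tp: (2.88, 2.36) for tp in TIMEPOINTS_H}

_RUPTURE_PROB = {"control": 0.80, "mu_0.5mM": 0.40, "mu_1mM": 0.03}

# Logistic expansion plateau by treatment (dose-dependent suppression)
# and by age (smaller, earlier peak in aged follicles).
_SIGMOID = {
    ("young", "control"): (1.0e5, 2.0e5, 1.2, 6.0),
    ("young", "mu_0.5mM"): (1.0e5, 1.6e5, 1.2, 6.0),
    ("young", "mu_1mM"): (1.0e5, 1.2e5, 1.2, 6.0),
    ("old", "control"): (0.9e5, 1.7e5, 1.2, 5.0),
    ("old", "mu_0.5mM"): (0.9e5, 1.4e5, 1.2, 5.0),
    ("old", "mu_1mM"): (0.9e5, 1.1e5, 1.2, 5.0),
}


def make_preset(group: str, timepoint_h: int, treatment: str = "control",
                seed: int = 0) -> GeneratorPreset:
    """Return the default preset for one cohort cell.

    Raises
    ------
    PresetError
        If any argument is outside its enumeration.
    """
    if group not in GROUPS:
        raise PresetError(f"unknown group {group!r}; expected one of {GROUPS}")
    if timepoint_h not in TIMEPOINTS_H:
        raise PresetError(
            f"unknown timepoint {timepoint_h!r}; expected one of {TIMEPOINTS_H}"
        )
    if treatment not in TREATMENTS:
        raise PresetError(
            f"unknown treatment {treatment!r}; expected one of {TREATMENTS}"
        )

    pressure_mean, pressure_sd = (
        _YOUNG_PRESSURE if group == "young" else _OLD_PRESSURE
    )[timepoint_h]
    # 4-MU abolishes the pressure rise: treated arms stay at the 0 h
    # baseline of their age group at every timepoint.
    if treatment != "control":
        pressure_mean, pressure_sd = (
            _YOUNG_PRESSURE if group == "young" else _OLD_PRESSURE
        )[0]

    thickness = _THICKNESS_BY_TP[timepoint_h]
    radius = _RADIUS_BY_TP[timepoint_h]
    return GeneratorPreset(
        group=group,
        timepoint_h=timepoint_h,
        treatment=treatment,
        pressure_mean=pressure_mean,
        pressure_sd=pressure_sd,
        wall_thickness_mean=thickness,
        thickness_asymmetry=0.3,
        follicle_radius_mean=radius,
        antrum_ratio_mean=_shell_antrum_ratio(radius, thickness),
        sigmoid_params=_SIGMOID[(group, treatment)],
        rupture_prob=_RUPTURE_PROB[treatment],
        seed=seed,
    )
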
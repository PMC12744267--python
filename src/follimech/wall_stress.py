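"""Laplace's-Law wall-stress estimation.

For a pressurized thin-walled sphere the circumferential wall stress is

    sigma = P * r / (2 * t)

with cavity pressure P, follicle radius r and wall thickness t. Cohort
estimates follow the source protocol: each follicle contributes its own
radius and area-weighted mean thickness, while the pressure is the
cohort-average measurement at that (group, timepoint).
"""

from __future__ import annotations

import pandas as pd

from .units import MMHG_TO_PA

__all__ = ["laplace_wall_stress", "cohort_wall_stress", "JoinError"]


class JoinError(KeyError):
    """A (group, timepoint) cell lacks a mean-pressure record."""


def laplace_wall_stress(pressure_pa: float, radius_um: float,
                        thickness_um: float) -> float:
    """Thin-wall Laplace stress, Pa.

    ``radius_um`` and ``thickness_um`` share a unit, so the result
    carries the unit of ``pressure_pa``.
    """
    if radius_um <= 0:
        raise ValueError("radius must be positive")
    if thickness_um <= 0:
        raise ValueError("thickness must be positive")
    return pressure_pa * radius_um / (2.0 * thickness_um)


def cohort_wall_stress(pressure_table: pd.DataFrame, oct_table: pd.DataFrame
                       ) -> pd.DataFrame:
    """Per-follicle wall stress from pressure and OCT morphometry tables.

    Parameters
    ----------
    pressure_table : DataFrame
        Needs ``group, timepoint_h, pressure_mmhg`` (one row per
        measured follicle); the (group, timepoint) means supply the P
        in Laplace's Law.
    oct_table : DataFrame
        Needs ``follicle_id, group, timepoint_h, radius_um,
        thickness_um`` (per-follicle morphometry).

    Returns
    -------
    DataFrame
        One row per OCT follicle with ``stress_pa``, ``stress_mmhg``
        (stress expressed in pressure units for traceability), and the
        pressure/radius/thickness inputs used.

    Raises
    ------
    JoinError
        Naming the (group, timepoint) cells that have OCT records but
        no pressure mean.
    """
    required_p = {"group", "timepoint_h", "pressure_mmhg"}
    required_o = {"follicle_id", "group", "timepoint_h", "radius_um",
                  "thickness_um"}
    if missing := required_p - set(pressure_table.columns):
        raise KeyError(f"pressure table missing columns {sorted(missing)}")
    if missing := required_o - set(oct_table.columns):
        raise KeyError(f"oct table missing columns {sorted(missing)}")

    means = (pressure_table.dropna(subset=["pressure_mmhg"])
             .groupby(["group", "timepoint_h"], as_index=False)["pressure_mmhg"]
             .mean()
             .rename(columns={"pressure_mmhg": "pressure_used_mmhg"}))
    merged = oct_table.merge(means, on=["group", "timepoint_h"], how="left")
    unmatched = merged[merged["pressure_used_mmhg"].isna()]
    if len(unmatched):
        keys = sorted({(r.group, r.timepoint_h) for r in unmatched.itertuples()})
        raise JoinError(f"no mean pressure for cells: {keys}")

    out = merged.copy()
    out["pressure_used_pa"] = out["pressure_used_mmhg"] * MMHG_TO_PA
    out["stress_pa"] = (out["pressure_used_pa"] * out["radius_um"]
                        / (2.0 * out["thickness_um"]))
    out["stress_mmhg"] = out["stress_pa"] / MMHG_TO_PA
    return out
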
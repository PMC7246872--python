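"""Garment-level derived clothing properties.

Turns manikin totals into the quantities a heat-strain model consumes: the
clothing area factor f_cl from projected photographic areas, the basic
(intrinsic) insulation I_cl = I_T - I_a/f_cl, the total evaporative resistance
R_et from isothermal heat-loss measurements (optionally corrected for the
evaporative cooling of the wet textile skin below the set-point), the
intrinsic evaporative resistance R_ecl, and the static moisture permeability
index i_m = (I_T/R_et)/Lewis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

from . import constants as c
from .phs import saturation_vp

__all__ = [
    "EnsembleProperties",
    "EvapZoneRecord",
    "clothing_area_factor",
    "basic_insulation",
    "evaporative_resistance_heat_loss",
    "permeability_index",
    "intrinsic_evap_resistance",
    "clo_to_si",
    "si_to_clo",
]


class ClothingValidationError(ValueError):
    pass


@dataclass(frozen=True)
class EnsembleProperties:
    """Whole-garment constants for one ensemble.

    Insulations in m2K/W, evaporative resistances in m2Pa/W; ``i_m`` is the
    dimensionless static moisture permeability index; ``mass`` (kg) is
    informational.
    """

    name: str
    f_cl: float
    i_t: float
    i_tr: float
    i_cl: float
    r_et: float
    r_ecl: float
    i_m: float
    mass: Optional[float] = None

    def __post_init__(self) -> None:
        if self.f_cl < 1:
            raise ClothingValidationError(f"{self.name}: f_cl must be >= 1")
        if not self.i_cl < self.i_t:
            raise ClothingValidationError(
                f"{self.name}: basic insulation must be below total insulation"
            )
        if not 0 < self.i_m <= 1:
            raise ClothingValidationError(
                f"{self.name}: i_m must lie in (0, 1], got {self.i_m}"
            )
        if not self.r_ecl < self.r_et:
            raise ClothingValidationError(
                f"{self.name}: intrinsic evaporative resistance must be below "
                f"the total"
            )

    @property
    def i_cl_clo(self) -> float:
        return si_to_clo(self.i_cl)


@dataclass(frozen=True)
class EvapZoneRecord:
    """One zone's isothermal sweating measurement.

    ``q_evap`` is the areal heat loss (W/m2) at the isothermal setting,
    ``t_manikin_surface`` the set-point (34 degC by convention),
    ``t_wet_skin`` the actual wet-textile-skin temperature (depressed below
    the set-point by evaporative cooling), and ``p_a`` the ambient water
    vapour pressure in kPa.
    """

    zone_id: str
    area: float
    q_evap: float
    t_manikin_surface: float = 34.0
    t_wet_skin: float = 34.0
    p_a: float = 1.0

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ClothingValidationError(
                f"zone {self.zone_id!r}: area must be > 0"
            )
        if self.q_evap <= 0:
            raise ClothingValidationError(
                f"zone {self.zone_id!r}: evaporative heat loss must be > 0"
            )


def clothing_area_factor(
    a_cl_front: float,
    a_cl_side: float,
    a_nude_front: float,
    a_nude_side: float,
) -> float:
    """Clothing area factor from front+side projected areas (any common unit).

    f_cl = (clothed front + side) / (nude front + side), floored at 1.0 with a
    warning, since a garment cannot shrink the radiating surface.
    """
    areas = (a_cl_front, a_cl_side, a_nude_front, a_nude_side)
    if any(a <= 0 for a in areas):
        raise ClothingValidationError(
            f"projected areas must be > 0, got {areas}"
        )
    ratio = (a_cl_front + a_cl_side) / (a_nude_front + a_nude_side)
    if ratio < 1.0:
        warnings.warn(
            f"projected-area ratio {ratio:.3f} < 1; flooring f_cl at 1.0",
            stacklevel=2,
        )
        return 1.0
    return ratio


def basic_insulation(i_t: float, i_a: float, f_cl: float) -> float:
    """Basic (intrinsic) clothing insulation I_cl = I_T - I_a/f_cl, m2K/W."""
    if i_t <= 0 or i_a <= 0 or f_cl < 1:
        raise ClothingValidationError(
            f"need I_T, I_a > 0 and f_cl >= 1, got ({i_t}, {i_a}, {f_cl})"
        )
    i_cl = i_t - i_a / f_cl
    if i_cl <= 0:
        raise ClothingValidationError(
            f"I_cl = {i_cl:.4f} <= 0: total insulation does not exceed the "
            f"boundary air layer"
        )
    return i_cl


def evaporative_resistance_heat_loss(
    rec: EvapZoneRecord, correction: str = "none"
) -> float:
    """Total evaporative resistance from the heat-loss method, m2Pa/W.

    R_et = (p_sat(t_eval) - p_a) * 1000 / q_evap, where the evaluation
    temperature is the manikin set-point (``correction="none"``) or the
    measured wet-textile-skin temperature (``correction="wet_skin_temp"``,
    accounting for evaporative cooling of the wet skin below the set-point).
    """
    if correction == "none":
        t_eval = rec.t_manikin_surface
    elif correction == "wet_skin_temp":
        t_eval = rec.t_wet_skin
    else:
        raise ClothingValidationError(f"unknown correction {correction!r}")
    p_sat = saturation_vp(t_eval)
    if p_sat <= rec.p_a:
        raise ClothingValidationError(
            f"zone {rec.zone_id!r}: saturation pressure at {t_eval} degC "
            f"({p_sat:.3f} kPa) does not exceed ambient {rec.p_a} kPa"
        )
    return (p_sat - rec.p_a) * 1000.0 / rec.q_evap


def permeability_index(i_t: float, r_et: float) -> float:
    """Static moisture permeability index i_m = (I_T/R_et)/(Lewis constant).

    Uses the manikin-lab Lewis relation of 16.65 K/kPa.  Dimensionless,
    clipped to (0, 1] with a warning when the raw value exceeds 1.
    """
    if i_t <= 0 or r_et <= 0:
        raise ClothingValidationError(
            f"I_T and R_et must be > 0, got ({i_t}, {r_et})"
        )
    i_m = (i_t / r_et) / (c.LEWIS_MANIKIN / 1000.0)
    if i_m > 1.0:
        warnings.warn(
            f"permeability index {i_m:.3f} > 1; clipping to 1.0", stacklevel=2
        )
        return 1.0
    return i_m


def intrinsic_evap_resistance(
    r_et: float, r_e_boundary: float, f_cl: float
) -> float:
    """Intrinsic evaporative resistance R_ecl = R_et - R_e,boundary/f_cl.

    The boundary term conventionally defaults to the measured wet-textile-skin
    total (8.2 m2Pa/W for this lab's skin).
    """
    if r_et <= 0 or r_e_boundary < 0 or f_cl < 1:
        raise ClothingValidationError(
            f"need R_et > 0, boundary >= 0, f_cl >= 1, got "
            f"({r_et}, {r_e_boundary}, {f_cl})"
        )
    r_ecl = r_et - r_e_boundary / f_cl
    if r_ecl <= 0:
        raise ClothingValidationError(
            f"R_ecl = {r_ecl:.3f} <= 0: total evaporative resistance does not "
            f"exceed the boundary layer"
        )
    return r_ecl


def clo_to_si(value: float) -> float:
    """clo -> m2K/W (1 clo = 0.155 m2K/W)."""
    if value < 0:
        raise ClothingValidationError(f"insulation cannot be negative: {value}")
    return value * c.CLO_TO_SI


def si_to_clo(value: float) -> float:
    """m2K/W -> clo."""
    if value < 0:
        raise ClothingValidationError(f"insulation cannot be negative: {value}")
    return value / c.CLO_TO_SI
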
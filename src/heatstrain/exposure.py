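"""Environmental preprocessing and the two exposure-evaluation drivers.

Converts field weather observations (globe temperature, relative humidity,
natural wet-bulb temperature) into the quantities the PHS model consumes
(mean radiant temperature, water vapour pressure) plus the WBGT index, and
drives the model either hour by hour over a weather day or over a fixed
high-humidity temperature x workload scenario grid.  Each prediction is an
independent run: no physiological state is carried between hours.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from . import constants as c
from .clothing import EnsembleProperties, si_to_clo
from .phs import PHSInputs, run_phs, saturation_vp

__all__ = [
    "WeatherRecord",
    "ScenarioGrid",
    "SubjectTask",
    "mean_radiant_from_globe",
    "vp_from_rh",
    "wbgt_outdoor",
    "hourly_dle",
    "humidity_scenario",
]


class WeatherValidationError(ValueError):
    pass


def mean_radiant_from_globe(t_g: float, t_a: float, v_a: float) -> float:
    """Mean radiant temperature from a 150 mm black-globe reading, degC.

    Forced-convection form:
    t_r = ((t_g+273)^4 + 2.5e8 * v_a^0.6 * (t_g - t_a))^0.25 - 273.
    """
    if v_a < 0:
        raise WeatherValidationError("air velocity cannot be negative")
    return (
        (t_g + 273.0) ** 4
        + c.GLOBE_FORCED_COEF * v_a**c.GLOBE_V_EXP * (t_g - t_a)
    ) ** 0.25 - 273.0


def vp_from_rh(t_a: float, rh: float) -> float:
    """Ambient water vapour pressure, kPa, from air temperature and RH (%)."""
    if not 0 <= rh <= 100:
        raise WeatherValidationError(f"RH must lie in [0, 100], got {rh}")
    return rh / 100.0 * saturation_vp(t_a)


def wbgt_outdoor(t_nw: float, t_g: float, t_a: float) -> float:
    """Outdoor WBGT index: 0.7 t_nw + 0.2 t_g + 0.1 t_a, degC."""
    return (
        c.WBGT_W_NATURAL_WET_BULB * t_nw
        + c.WBGT_W_GLOBE * t_g
        + c.WBGT_W_AIR * t_a
    )


@dataclass(frozen=True)
class WeatherRecord:
    """One hour's environmental observations.

    At least one of (t_g, t_r) and one of (RH, p_a) must be present; when
    both members of a pair are given, the derived quantity (t_r, p_a) wins
    unless ``resolve`` is told to recompute.
    """

    time: str
    t_a: float
    v_a: float
    t_g: Optional[float] = None
    t_r: Optional[float] = None
    t_nw: Optional[float] = None
    rh: Optional[float] = None
    p_a: Optional[float] = None

    def __post_init__(self) -> None:
        if self.t_g is None and self.t_r is None:
            raise WeatherValidationError(
                f"hour {self.time!r}: need globe or mean radiant temperature"
            )
        if self.rh is None and self.p_a is None:
            raise WeatherValidationError(
                f"hour {self.time!r}: need RH or vapour pressure"
            )
        if self.rh is not None and not 0 <= self.rh <= 100:
            raise WeatherValidationError(
                f"hour {self.time!r}: RH out of [0, 100]"
            )
        if self.p_a is not None and self.p_a > saturation_vp(self.t_a) + 1e-9:
            raise WeatherValidationError(
                f"hour {self.time!r}: vapour pressure {self.p_a} kPa exceeds "
                f"saturation at {self.t_a} degC"
            )

    def resolve(self, recompute_tr: bool = False) -> tuple[float, float]:
        """(t_r, p_a) for this hour, deriving what is absent."""
        if self.t_r is not None and not recompute_tr:
            t_r = self.t_r
        elif self.t_g is not None:
            t_r = mean_radiant_from_globe(self.t_g, self.t_a, self.v_a)
        else:
            t_r = self.t_r
        p_a = self.p_a if self.p_a is not None else vp_from_rh(self.t_a, self.rh)
        return t_r, p_a

    def wbgt(self) -> Optional[float]:
        if self.t_nw is None or self.t_g is None:
            return None
        return wbgt_outdoor(self.t_nw, self.t_g, self.t_a)


@dataclass(frozen=True)
class SubjectTask:
    """Subject anthropometry and task parameters shared across runs."""

    mass: float = 70.0
    height: float = 1.75
    posture: str = "standing"
    acclimatized: bool = True
    drink_free: bool = True
    v_walk: Optional[float] = 0.5
    walk_angle_deg: Optional[float] = None
    duration: int = 480
    water_loss_fraction: Optional[float] = None


def _inputs_for(
    ensemble: EnsembleProperties,
    subject: SubjectTask,
    t_a: float,
    t_r: float,
    p_a: float,
    v_a: float,
    m_watts: float,
) -> PHSInputs:
    return PHSInputs(
        t_a=t_a,
        t_r=t_r,
        p_a=p_a,
        v_a=v_a,
        m_watts=m_watts,
        i_cl_static=si_to_clo(ensemble.i_cl),
        i_m_static=ensemble.i_m,
        mass=subject.mass,
        height=subject.height,
        posture=subject.posture,
        acclimatized=subject.acclimatized,
        drink_free=subject.drink_free,
        v_walk=subject.v_walk,
        walk_angle_deg=subject.walk_angle_deg,
        duration=subject.duration,
        water_loss_fraction=subject.water_loss_fraction,
    )


def hourly_dle(
    weather: Sequence[WeatherRecord],
    ensemble: EnsembleProperties,
    m_levels: Sequence[float],
    subject: SubjectTask = SubjectTask(),
    recompute_tr: bool = False,
) -> pd.DataFrame:
    """Hour-by-hour DLE table over a weather day.

    One independent PHS run per (hour, metabolic level); returns one row per
    run with both DLE criteria and the operative (minimum) limit.
    """
    if not weather:
        raise WeatherValidationError("empty weather series")
    rows = []
    for rec in weather:
        t_r, p_a = rec.resolve(recompute_tr=recompute_tr)
        for m in m_levels:
            res = run_phs(
                _inputs_for(ensemble, subject, rec.t_a, t_r, p_a, rec.v_a, m)
            )
            rows.append(
                {
                    "time": rec.time,
                    "t_a_C": rec.t_a,
                    "t_r_C": t_r,
                    "p_a_kPa": p_a,
                    "v_a_ms": rec.v_a,
                    "M_W": m,
                    "DLE_tre_min": res.dle_tre,
                    "DLE_water_min": res.dle_water,
                    "DLE_min": res.dle_operative,
                    "final_water_loss_g": res.final_water_loss_g,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ScenarioGrid:
    """Fictive high-humidity scenario: air temperatures x workloads.

    RH is held constant (70% by default) so the vapour pressure tracks air
    temperature; mean radiant temperature and wind are fixed (70 degC, 2 m/s
    defaults, equivalent to a constant 44 degC globe reading at 34 degC air).
    """

    t_a_values: tuple[float, ...] = tuple(range(28, 37))
    m_levels: tuple[float, ...] = (200.0, 250.0, 300.0)
    rh: float = 70.0
    t_r: float = 70.0
    v_a: float = 2.0

    def __post_init__(self) -> None:
        if not self.t_a_values or not self.m_levels:
            raise WeatherValidationError("scenario grid must be nonempty")
        if not 0 <= self.rh <= 100:
            raise WeatherValidationError("scenario RH out of [0, 100]")


def humidity_scenario(
    grid: ScenarioGrid,
    ensemble: EnsembleProperties,
    subject: SubjectTask = SubjectTask(),
) -> pd.DataFrame:
    """Full-factorial PHS runs over the scenario grid.

    Returns one row per (t_a, M) with both DLE criteria and the operative
    limit min(DLE_tre, DLE_water) — the value to use as the allowed work
    limit in practice.
    """
    rows = []
    for t_a in grid.t_a_values:
        p_a = vp_from_rh(t_a, grid.rh)
        for m in grid.m_levels:
            res = run_phs(
                _inputs_for(ensemble, subject, t_a, grid.t_r, p_a, grid.v_a, m)
            )
            rows.append(
                {
                    "t_a_C": t_a,
                    "RH_pct": grid.rh,
                    "p_a_kPa": p_a,
                    "t_r_C": grid.t_r,
                    "v_a_ms": grid.v_a,
                    "M_W": m,
                    "DLE_tre_min": res.dle_tre,
                    "DLE_water_min": res.dle_water,
                    "DLE_min": res.dle_operative,
                    "final_water_loss_g": res.final_water_loss_g,
                }
            )
    return pd.DataFrame(rows)
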
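"""Synthetic manikin datasets and weather days with known ground truth.

The zone generator inverts the insulation definition: given a per-zone truth
map it emits areal heat losses ``q = dT / I_true`` at the laboratory gradient
(34 degC surface over 20 degC ambient), optionally perturbed multiplicatively,
two replicates per condition.  The weather generator emits a clipped-sinusoid
diurnal day whose extremes default to the ranges observed in a sugarcane
field (air 18.6-36.4 degC, globe 20.5-52.1 degC, wind steady at 2 m/s), with
relative humidity in anti-phase with air temperature.  Both generators are
pure functions of their spec, seed included.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .exposure import WeatherRecord
from .manikin import DEFAULT_AREA_TABLE, ZoneAreaTable, ZoneRecord

__all__ = [
    "SyntheticSpec",
    "DEFAULT_ZONE_TRUTHS",
    "DEFAULT_DYNAMIC_RATIOS",
    "generate_zone_dataset",
    "generate_weather_day",
]

#: Default static per-zone insulation truths (m2K/W): the boundary air layer
#: around a nude manikin, zone values mirroring the published air-layer
#: column so that generated data resemble the nude-manikin test.
DEFAULT_ZONE_TRUTHS: Mapping[str, float] = {
    "Head": 0.174,
    "Chest": 0.105,
    "Back": 0.093,
    "Belly": 0.093,
    "Buttocks": 0.070,
    "L.Upper arm": 0.105,
    "R.Upper arm": 0.105,
    "L.Forearm": 0.101,
    "R.Forearm": 0.101,
    "L.Hand": 0.108,
    "R.Hand": 0.093,
    "L.Thigh": 0.095,
    "R.Thigh": 0.095,
    "L.Lower leg": 0.082,
    "R.Lower leg": 0.082,
    "L.Foot": 0.103,
    "R.Foot": 0.103,
}

#: Default dynamic/static ratios per zone (walking reduces the air layer most
#: at swinging extremities, least at the head).
DEFAULT_DYNAMIC_RATIOS: Mapping[str, float] = {
    "Head": 1.06,
    "Chest": 0.99,
    "Back": 0.97,
    "Belly": 0.84,
    "Buttocks": 0.91,
    "L.Upper arm": 0.74,
    "R.Upper arm": 0.74,
    "L.Forearm": 0.55,
    "R.Forearm": 0.55,
    "L.Hand": 0.51,
    "R.Hand": 0.54,
    "L.Thigh": 0.84,
    "R.Thigh": 0.84,
    "L.Lower leg": 0.62,
    "R.Lower leg": 0.91,
    "L.Foot": 0.55,
    "R.Foot": 0.55,
}


@dataclass(frozen=True)
class WeatherSpec:
    """Diurnal ranges for the synthetic weather day."""

    t_a_min: float = 18.6
    t_a_max: float = 36.4
    t_g_min: float = 20.5
    t_g_max: float = 52.1
    rh_min: float = 40.0
    rh_max: float = 90.0
    v_a: float = 2.0
    hours: int = 24
    peak_hour: float = 14.0

    def __post_init__(self) -> None:
        for lo, hi, what in (
            (self.t_a_min, self.t_a_max, "t_a"),
            (self.t_g_min, self.t_g_max, "t_g"),
            (self.rh_min, self.rh_max, "RH"),
        ):
            if not lo < hi:
                raise ValueError(f"{what}: need min < max, got ({lo}, {hi})")
        if self.hours < 1:
            raise ValueError("need at least one hour")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic generators."""

    seed: int = 0
    zone_truths: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ZONE_TRUTHS)
    )
    dynamic_ratios: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DYNAMIC_RATIOS)
    )
    noise_sd: float = 0.0
    n_replicates: int = 2
    t_surface: float = 34.0
    t_ambient: float = 20.0
    layer: str = "nude_air_layer"
    area_table: ZoneAreaTable = DEFAULT_AREA_TABLE
    weather: WeatherSpec = WeatherSpec()

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        missing = set(self.zone_truths) - set(self.area_table.areas)
        if missing:
            raise ValueError(
                f"zone truths reference zones without areas: {sorted(missing)}"
            )


def generate_zone_dataset(spec: SyntheticSpec) -> list[ZoneRecord]:
    """Zone records with known ground-truth insulation.

    For every zone and condition, ``q = dT / I_true`` perturbed by a
    multiplicative factor ``max(1 + sd*N(0,1), 0.1)``; two replicates by
    default.  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    dt = spec.t_surface - spec.t_ambient
    if dt <= 0:
        raise ValueError("surface temperature must exceed ambient")
    records = []
    for zone in sorted(spec.zone_truths):
        truth = spec.zone_truths[zone]
        per_cond = {
            "static": truth,
            "dynamic": truth * spec.dynamic_ratios.get(zone, 0.8),
        }
        for cond, ins in per_cond.items():
            for rep in range(1, spec.n_replicates + 1):
                factor = max(1.0 + spec.noise_sd * rng.standard_normal(), 0.1)
                records.append(
                    ZoneRecord(
                        zone_id=zone,
                        area=spec.area_table.areas[zone],
                        t_surface=spec.t_surface,
                        t_ambient=spec.t_ambient,
                        q=dt / ins * factor,
                        condition=cond,
                        layer=spec.layer,
                        replicate=rep,
                    )
                )
    return records


def _wet_bulb_stull(t_a: float, rh: float) -> float:
    """Wet-bulb temperature approximation (Stull 2011), degC."""
    return (
        t_a * math.atan(0.151977 * math.sqrt(rh + 8.313659))
        + math.atan(t_a + rh)
        - math.atan(rh - 1.676331)
        + 0.00391838 * rh**1.5 * math.atan(0.023101 * rh)
        - 4.686035
    )


def generate_weather_day(spec: SyntheticSpec) -> list[WeatherRecord]:
    """A sinusoidal diurnal weather day hitting the configured extremes.

    Air and globe temperatures share the phase (minimum in the small hours,
    maximum at ``peak_hour``); relative humidity is in anti-phase.  Wind is
    constant.  A natural-wet-bulb estimate is included for WBGT computation.
    """
    w = spec.weather
    records = []
    for h in range(w.hours):
        # 0 at the daily minimum, 1 at the peak
        lam = (1.0 + math.cos(2.0 * math.pi * (h - w.peak_hour) / 24.0)) / 2.0
        t_a = w.t_a_min + (w.t_a_max - w.t_a_min) * lam
        t_g = w.t_g_min + (w.t_g_max - w.t_g_min) * lam
        rh = w.rh_max - (w.rh_max - w.rh_min) * lam
        records.append(
            WeatherRecord(
                time=f"{h:02d}:00",
                t_a=t_a,
                t_g=max(t_g, t_a),
                t_nw=_wet_bulb_stull(t_a, rh),
                rh=rh,
                v_a=w.v_a,
            )
        )
    return records
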
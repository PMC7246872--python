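"""CSV / YAML readers and writers.

One tabular dialect throughout: comma-separated, UTF-8, decimal point, unit
suffixes embedded in headers so clo and SI insulation cannot be confused.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
import yaml

from .clothing import EnsembleProperties
from .exposure import WeatherRecord
from .manikin import ZoneAreaTable, ZoneRecord

__all__ = [
    "ZONE_CSV_COLUMNS",
    "WEATHER_CSV_COLUMNS",
    "read_zone_csv",
    "write_zone_csv",
    "read_weather_csv",
    "write_weather_csv",
    "read_area_table",
    "write_area_table",
    "read_ensemble_properties",
    "write_ensemble_properties",
    "write_insulation_report",
]

PathLike = Union[str, Path]

ZONE_CSV_COLUMNS = [
    "zone_id", "area_m2", "t_surface_C", "t_ambient_C", "q_Wm2",
    "condition", "layer", "replicate",
]

WEATHER_CSV_COLUMNS = [
    "time", "t_a_C", "t_g_C", "t_r_C", "t_nw_C", "RH_pct", "p_a_kPa",
    "v_a_ms",
]


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: PathLike) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")


def read_zone_csv(path: PathLike) -> list[ZoneRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ZONE_CSV_COLUMNS, path)
    return [
        ZoneRecord(
            zone_id=str(row.zone_id),
            area=float(row.area_m2),
            t_surface=float(row.t_surface_C),
            t_ambient=float(row.t_ambient_C),
            q=float(row.q_Wm2),
            condition=str(row.condition),
            layer=str(row.layer),
            replicate=int(row.replicate),
        )
        for row in df.itertuples(index=False)
    ]


def write_zone_csv(records: Iterable[ZoneRecord], path: PathLike) -> None:
    pd.DataFrame(
        [
            (r.zone_id, r.area, r.t_surface, r.t_ambient, r.q, r.condition,
             r.layer, r.replicate)
            for r in records
        ],
        columns=ZONE_CSV_COLUMNS,
    ).to_csv(path, index=False, float_format="%.17g")


def _opt(value) -> Optional[float]:
    """None for blank/NaN cells."""
    if value is None:
        return None
    value = float(value)
    return None if math.isnan(value) else value


def read_weather_csv(path: PathLike) -> list[WeatherRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["time", "t_a_C", "v_a_ms"], path)
    for col in WEATHER_CSV_COLUMNS:
        if col not in df.columns:
            df[col] = float("nan")
    return [
        WeatherRecord(
            time=str(row.time),
            t_a=float(row.t_a_C),
            v_a=float(row.v_a_ms),
            t_g=_opt(row.t_g_C),
            t_r=_opt(row.t_r_C),
            t_nw=_opt(row.t_nw_C),
            rh=_opt(row.RH_pct),
            p_a=_opt(row.p_a_kPa),
        )
        for row in df.itertuples(index=False)
    ]


def write_weather_csv(records: Iterable[WeatherRecord], path: PathLike) -> None:
    pd.DataFrame(
        [
            (r.time, r.t_a, r.t_g, r.t_r, r.t_nw, r.rh, r.p_a, r.v_a)
            for r in records
        ],
        columns=WEATHER_CSV_COLUMNS,
    ).to_csv(path, index=False, float_format="%.17g")


def read_area_table(path: PathLike) -> ZoneAreaTable:
    """Zone areas and region definitions from YAML.

    Expected shape::

        areas: {Head: 0.13, Chest: 0.17, ...}
        regions: {Hands: [L.Hand, R.Hand], ...}
    """
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "areas" not in data:
        raise ValueError(f"{path}: expected a mapping with an 'areas' key")
    return ZoneAreaTable(
        areas={str(k): float(v) for k, v in data["areas"].items()},
        regions={
            str(k): frozenset(str(z) for z in v)
            for k, v in data.get("regions", {}).items()
        },
    )


def write_area_table(table: ZoneAreaTable, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(
            {
                "areas": dict(table.areas),
                "regions": {k: sorted(v) for k, v in table.regions.items()},
            },
            fh,
            sort_keys=True,
        )


_ENSEMBLE_FIELDS = [
    ("name", str), ("f_cl", float), ("i_t", float), ("i_tr", float),
    ("i_cl", float), ("r_et", float), ("r_ecl", float), ("i_m", float),
    ("mass", float),
]


def write_ensemble_properties(props: EnsembleProperties, path: PathLike) -> None:
    """Flat ``key = value`` file consumable by the PHS driver."""
    with open(path, "w", encoding="utf-8") as fh:
        for key, _ in _ENSEMBLE_FIELDS:
            value = getattr(props, key)
            if value is not None:
                fh.write(f"{key} = {value}\n")


def read_ensemble_properties(path: PathLike) -> EnsembleProperties:
    values: dict[str, object] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            key, _, raw = line.partition("=")
            values[key.strip()] = raw.strip()
    kwargs = {}
    for key, cast in _ENSEMBLE_FIELDS:
        if key in values:
            kwargs[key] = cast(values[key])
    return EnsembleProperties(**kwargs)


def write_insulation_report(table: pd.DataFrame, path: PathLike) -> None:
    """Report-style insulation table: 3 dp insulation, 2 dp ratio, 1 dp %."""
    out = table.copy()
    for col in ("I_T", "I_Tr"):
        out[col] = out[col].round(3)
    out["ratio"] = out["ratio"].round(2)
    out["diff_pct"] = out["diff_pct"].round(1)
    out.to_csv(path, index=False)
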
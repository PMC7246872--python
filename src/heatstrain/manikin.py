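"""Zone-level thermal-manikin calculus.

A heated, body-shaped manikin measures areal heat loss zone by zone; dividing
the surface-to-ambient temperature gradient by the areal heat loss gives each
zone's total thermal insulation.  Zone values are combined into regional and
whole-body values either in *parallel* (summing heat losses at a common
gradient — the area-weighted harmonic mean preferred by ISO 15831) or in
*serial* (the area-weighted arithmetic mean).  Static (standing) and dynamic
(walking) conditions are compared via the resultant-to-static ratio and the
percentage change.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ZoneRecord",
    "ZoneAreaTable",
    "DEFAULT_AREA_TABLE",
    "zone_insulation",
    "aggregate",
    "aggregate_excluding",
    "dynamic_comparison",
    "average_replicates",
    "build_insulation_table",
]

CONDITIONS = ("static", "dynamic")
LAYERS = ("nude_air_layer", "textile_skin", "ensemble")


class ManikinValidationError(ValueError):
    """Raised when a zone record or an aggregation request is inconsistent."""


@dataclass(frozen=True)
class ZoneRecord:
    """One manikin zone's measurement under one condition.

    Parameters
    ----------
    zone_id:
        Zone label, e.g. ``"Chest"`` or ``"L.Hand"``.
    area:
        Zone surface area, m2.
    t_surface, t_ambient:
        Manikin surface and ambient air temperature, degC.
    q:
        Areal heat loss, W/m2.
    condition:
        ``"static"`` (standing) or ``"dynamic"`` (walking).
    layer:
        What covered the manikin: ``"nude_air_layer"``, ``"textile_skin"``
        (simulated sweating skin) or ``"ensemble"`` (the garment set).
    replicate:
        Replicate index, >= 1.
    """

    zone_id: str
    area: float
    t_surface: float
    t_ambient: float
    q: float
    condition: str = "static"
    layer: str = "ensemble"
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ManikinValidationError(
                f"zone {self.zone_id!r}: area must be > 0, got {self.area}"
            )
        if self.condition not in CONDITIONS:
            raise ManikinValidationError(
                f"zone {self.zone_id!r}: unknown condition {self.condition!r}"
            )
        if self.layer not in LAYERS:
            raise ManikinValidationError(
                f"zone {self.zone_id!r}: unknown layer {self.layer!r}"
            )
        if self.replicate < 1:
            raise ManikinValidationError(
                f"zone {self.zone_id!r}: replicate must be >= 1"
            )


def zone_insulation(rec: ZoneRecord) -> float:
    """Total insulation of one zone, m2K/W: (t_surface - t_ambient) / q."""
    if rec.q <= 0:
        raise ManikinValidationError(
            f"zone {rec.zone_id!r}: heat loss must be > 0 for an insulation "
            f"test, got q={rec.q}"
        )
    dt = rec.t_surface - rec.t_ambient
    if dt <= 0:
        raise ManikinValidationError(
            f"zone {rec.zone_id!r}: inverted temperature gradient "
            f"(t_surface={rec.t_surface}, t_ambient={rec.t_ambient})"
        )
    return dt / rec.q


def aggregate(
    zones: Sequence[tuple[float, float]], method: str = "parallel"
) -> float:
    """Combine per-zone (insulation, area) pairs into one value, m2K/W.

    ``parallel`` sums heat losses at a common gradient, ``I = sum(A) /
    sum(A/I)`` (area-weighted harmonic mean); ``serial`` is the area-weighted
    arithmetic mean ``sum(A*I)/sum(A)``.
    """
    zones = list(zones)
    if not zones:
        raise ManikinValidationError("cannot aggregate an empty zone set")
    for ins, area in zones:
        if ins <= 0 or area <= 0:
            raise ManikinValidationError(
                f"insulations and areas must be > 0, got ({ins}, {area})"
            )
    total_area = sum(a for _, a in zones)
    if method == "parallel":
        return total_area / sum(a / i for i, a in zones)
    if method == "serial":
        return sum(a * i for i, a in zones) / total_area
    raise ManikinValidationError(f"unknown aggregation method {method!r}")


def dynamic_comparison(i_t: float, i_tr: float) -> tuple[float, float]:
    """Resultant/static ratio and percentage change for one insulation pair.

    Returns ``(I_Tr/I_T, 100*(I_Tr - I_T)/I_T)``.  Reports conventionally
    round the ratio to 2 decimals and the difference to 1.
    """
    if i_t <= 0 or i_tr <= 0:
        raise ManikinValidationError(
            f"insulations must be > 0, got ({i_t}, {i_tr})"
        )
    return i_tr / i_t, 100.0 * (i_tr - i_t) / i_t


# --- zone areas and regions -------------------------------------------------


@dataclass(frozen=True)
class ZoneAreaTable:
    """Zone surface areas and the region definitions built from them."""

    areas: Mapping[str, float]
    regions: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for zone, a in self.areas.items():
            if a <= 0:
                raise ManikinValidationError(f"zone {zone!r}: area must be > 0")
        for name, members in self.regions.items():
            missing = set(members) - set(self.areas)
            if missing:
                raise ManikinValidationError(
                    f"region {name!r} references unknown zones {sorted(missing)}"
                )

    @property
    def total_area(self) -> float:
        return sum(self.areas.values())

    @property
    def zone_ids(self) -> frozenset[str]:
        return frozenset(self.areas)


def _pairs(regions: Mapping[str, Iterable[str]]) -> dict[str, frozenset[str]]:
    return {k: frozenset(v) for k, v in regions.items()}


#: Approximate 17-zone area table for a male-shaped manikin (~1.77 m2).  The
#: zone split and the region row labels follow the usual clothing-lab layout;
#: the individual areas are documented approximations and fully configurable.
DEFAULT_AREA_TABLE = ZoneAreaTable(
    areas={
        "Head": 0.13,
        "Chest": 0.17,
        "Back": 0.17,
        "Belly": 0.12,
        "Buttocks": 0.12,
        "L.Upper arm": 0.08,
        "R.Upper arm": 0.08,
        "L.Forearm": 0.06,
        "R.Forearm": 0.06,
        "L.Hand": 0.045,
        "R.Hand": 0.045,
        "L.Thigh": 0.16,
        "R.Thigh": 0.16,
        "L.Lower leg": 0.11,
        "R.Lower leg": 0.11,
        "L.Foot": 0.06,
        "R.Foot": 0.06,
    },
    regions=_pairs(
        {
            "Hands": ["L.Hand", "R.Hand"],
            "Feet": ["L.Foot", "R.Foot"],
            "Upper arms": ["L.Upper arm", "R.Upper arm"],
            "Lower Arms": ["L.Forearm", "R.Forearm"],
            "Arms": ["L.Upper arm", "R.Upper arm", "L.Forearm", "R.Forearm"],
            "Thighs": ["L.Thigh", "R.Thigh"],
            "Lower legs": ["L.Lower leg", "R.Lower leg"],
            "Legs": ["L.Thigh", "R.Thigh", "L.Lower leg", "R.Lower leg"],
            "Torso": ["Chest", "Back", "Belly", "Buttocks"],
        }
    ),
)

#: zones dropped for the conventional "Head, hands & feet excluded" total.
EXTREMITY_ZONES = frozenset(
    {"Head", "L.Hand", "R.Hand", "L.Foot", "R.Foot"}
)


def aggregate_excluding(
    zones: Mapping[str, tuple[float, float]],
    exclude: Iterable[str],
    method: str = "parallel",
) -> float:
    """Aggregate ``zone_id -> (insulation, area)`` leaving out ``exclude``.

    The areas of the remaining zones carry their own weights, i.e. the
    complement is renormalised implicitly by the aggregation formula.
    """
    exclude = set(exclude)
    unknown = exclude - set(zones)
    if unknown:
        raise ManikinValidationError(
            f"exclusion names unknown zones {sorted(unknown)}"
        )
    kept = [v for z, v in zones.items() if z not in exclude]
    if not kept:
        raise ManikinValidationError("exclusion leaves no zones to aggregate")
    return aggregate(kept, method=method)


# --- replicate averaging and table assembly ---------------------------------


def average_replicates(records: Iterable[ZoneRecord]) -> list[ZoneRecord]:
    """Arithmetic mean of replicate measurements per (zone, condition, layer).

    Temperatures and heat losses are averaged; areas must agree across
    replicates of the same zone.
    """
    groups: dict[tuple[str, str, str], list[ZoneRecord]] = {}
    for rec in records:
        groups.setdefault((rec.zone_id, rec.condition, rec.layer), []).append(rec)
    out = []
    for (zone, cond, layer), recs in groups.items():
        areas = {r.area for r in recs}
        if len(areas) > 1:
            raise ManikinValidationError(
                f"zone {zone!r}: replicates disagree on area: {sorted(areas)}"
            )
        n = len(recs)
        out.append(
            replace(
                recs[0],
                t_surface=sum(r.t_surface for r in recs) / n,
                t_ambient=sum(r.t_ambient for r in recs) / n,
                q=sum(r.q for r in recs) / n,
                replicate=1,
            )
        )
    return out


def build_insulation_table(
    records: Iterable[ZoneRecord],
    areas: ZoneAreaTable = DEFAULT_AREA_TABLE,
    method: str = "parallel",
    layer: str = "ensemble",
    sort_by_diff: bool = True,
) -> pd.DataFrame:
    """Zone / region / whole-body insulation table for one layer.

    Replicates are averaged first; each row carries the static total
    insulation ``I_T``, the dynamic (walking) resultant ``I_Tr``, their ratio
    and the percentage difference.  Region rows and the ``Total`` and
    ``Head, hands & feet excluded`` rows are parallel (or serial)
    aggregates of the zone values.
    """
    recs = [r for r in average_replicates(records) if r.layer == layer]
    by_cond: dict[str, dict[str, float]] = {"static": {}, "dynamic": {}}
    for rec in recs:
        by_cond[rec.condition][rec.zone_id] = zone_insulation(rec)

    zones = sorted(set(by_cond["static"]) | set(by_cond["dynamic"]))
    missing = [
        z
        for z in zones
        if z not in by_cond["static"] or z not in by_cond["dynamic"]
    ]
    if missing:
        raise ManikinValidationError(
            f"zones missing a static or dynamic measurement: {missing}"
        )
    unknown = [z for z in zones if z not in areas.areas]
    if unknown:
        raise ManikinValidationError(
            f"zones without a configured area: {unknown}"
        )

    def pair_map(subset: Iterable[str], cond: str) -> Mapping[str, tuple[float, float]]:
        return {z: (by_cond[cond][z], areas.areas[z]) for z in subset}

    rows = []

    def add_row(label: str, kind: str, i_t: float, i_tr: float) -> None:
        ratio, diff = dynamic_comparison(i_t, i_tr)
        rows.append(
            {"label": label, "kind": kind, "I_T": i_t, "I_Tr": i_tr,
             "ratio": ratio, "diff_pct": diff}
        )

    for z in zones:
        add_row(z, "zone", by_cond["static"][z], by_cond["dynamic"][z])
    for region, members in areas.regions.items():
        members = members & set(zones)
        if not members:
            continue
        add_row(
            region,
            "region",
            aggregate(list(pair_map(members, "static").values()), method),
            aggregate(list(pair_map(members, "dynamic").values()), method),
        )
    add_row(
        "Total",
        "total",
        aggregate(list(pair_map(zones, "static").values()), method),
        aggregate(list(pair_map(zones, "dynamic").values()), method),
    )
    excl = EXTREMITY_ZONES & set(zones)
    if excl and excl != set(zones):
        add_row(
            "Head, hands & feet excluded",
            "total",
            aggregate_excluding(pair_map(zones, "static"), excl, method),
            aggregate_excluding(pair_map(zones, "dynamic"), excl, method),
        )

    table = pd.DataFrame(rows)
    if sort_by_diff:
        table = table.sort_values("diff_pct", kind="stable", ignore_index=True)
    return table
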
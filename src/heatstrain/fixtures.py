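"""Embedded reference tables for the two studied ensembles.

These are the published laboratory values for the sugarcane-cutter (SC) and
chemical-sprayer (CP) outfits measured on the 17-zone manikin: the model
input table (``table1_sc``/``table1_cp``), the static/dynamic insulation
table (``table2``, m2K/W) and the corrected total evaporative resistance
table (``table3``, m2Pa/W).  They serve as stored measurement data — the
package's calculus is tested against them, and the packaged SC/CP ensembles
are built from them.
"""

from __future__ import annotations

from typing import Any

import pandas as pd

from .clothing import EnsembleProperties, clo_to_si

__all__ = ["load_fixture", "ensemble_properties", "FIXTURE_NAMES"]

#: PHS input parameters per ensemble (the published model-input table).
_TABLE1 = {
    "sc": {
        "name": "sugarcane cutter",
        "acclimatized": True,
        "drink_free": True,
        "height_m": 1.75,
        "mass_kg": 70.0,
        "body_surface_area_m2": 1.84,
        "posture": "standing",
        "t_a_C": 34.0,
        "t_a_range_C": (28.0, 36.0),
        "v_a_ms": 2.0,
        "m_levels_W": (250.0, 300.0, 350.0),
        "i_cl_clo": 0.69,
        "i_m": 0.55,
        "reflective_fraction": 0.0,
        "v_walk_ms": 0.5,
        "walk_angle_known": False,
        "w_mech_W": 0.0,
    },
    "cp": {
        "name": "chemical sprayer",
        "acclimatized": True,
        "drink_free": True,
        "height_m": 1.75,
        "mass_kg": 70.0,
        "body_surface_area_m2": 1.84,
        "posture": "standing",
        "t_a_C": 34.0,
        "t_a_range_C": (28.0, 36.0),
        "v_a_ms": 2.0,
        "m_levels_W": (200.0, 250.0, 300.0),
        "i_cl_clo": 1.14,
        "i_m": 0.19,
        "reflective_fraction": 0.0,
        "v_walk_ms": 0.5,
        "walk_angle_known": False,
        "w_mech_W": 0.0,
    },
}

#: Static/dynamic insulation per body part (m2K/W): air layer (AL), textile
#: skin (TS, static only), SC and CP ensembles; ratios and percent changes as
#: published.  Rows are ordered by the AL percentage difference.
_TABLE2_COLUMNS = [
    "label", "AL_I_T", "AL_I_Tr", "AL_diff_pct", "TS_I_T",
    "SC_I_T", "SC_I_Tr", "SC_ratio", "SC_diff_pct",
    "CP_I_T", "CP_I_Tr", "CP_ratio", "CP_diff_pct",
]
_TABLE2_ROWS = [
    ("L.Hand", 0.108, 0.055, -48.7, 0.135, 0.180, 0.114, 0.63, -36.5, 0.181, 0.123, 0.68, -32.1),
    ("Hands", 0.100, 0.053, -47.5, 0.132, 0.137, 0.077, 0.56, -44.0, 0.172, 0.115, 0.67, -33.3),
    ("R.Hand", 0.093, 0.050, -46.5, 0.129, 0.109, 0.057, 0.52, -47.9, 0.165, 0.108, 0.65, -34.8),
    ("Feet", 0.103, 0.057, -44.7, 0.122, 0.181, 0.144, 0.80, -20.0, 0.208, 0.149, 0.72, -28.1),
    ("Lower Arms", 0.101, 0.056, -44.2, 0.142, 0.172, 0.105, 0.61, -39.3, 0.259, 0.165, 0.64, -36.1),
    ("L.Lower leg", 0.082, 0.051, -38.3, 0.111, 0.168, 0.128, 0.76, -24.0, 0.269, 0.205, 0.76, -23.8),
    ("Arms", 0.104, 0.069, -33.4, 0.147, 0.194, 0.115, 0.59, -40.5, 0.258, 0.160, 0.62, -38.1),
    ("Upper arms", 0.105, 0.078, -25.8, 0.149, 0.209, 0.122, 0.59, -41.4, 0.259, 0.158, 0.61, -39.3),
    ("Lower legs", 0.082, 0.063, -23.2, 0.116, 0.181, 0.147, 0.81, -18.9, 0.255, 0.212, 0.83, -16.9),
    ("Total", 0.098, 0.076, -22.0, 0.131, 0.191, 0.143, 0.75, -25.3, 0.257, 0.188, 0.73, -26.8),
    ("Legs", 0.089, 0.071, -19.8, 0.118, 0.206, 0.154, 0.74, -25.6, 0.287, 0.205, 0.71, -28.6),
    ("Head, hands & feet excluded", 0.093, 0.076, -18.4, 0.131, 0.195, 0.146, 0.75, -25.3, 0.278, 0.200, 0.72, -28.3),
    ("Belly", 0.093, 0.078, -16.2, 0.121, 0.331, 0.261, 0.79, -21.1, 0.457, 0.322, 0.70, -29.6),
    ("Thighs", 0.095, 0.080, -15.2, 0.121, 0.229, 0.160, 0.70, -29.9, 0.316, 0.202, 0.64, -35.9),
    ("R.Lower leg", 0.082, 0.075, -8.1, 0.121, 0.194, 0.166, 0.86, -14.4, 0.241, 0.219, 0.91, -9.2),
    ("Buttocks", 0.070, 0.064, -7.9, 0.107, 0.253, 0.220, 0.87, -13.1, 0.396, 0.281, 0.71, -29.1),
    ("Torso", 0.092, 0.086, -6.3, 0.135, 0.187, 0.163, 0.87, -12.8, 0.283, 0.226, 0.80, -20.2),
    ("Back", 0.093, 0.090, -4.0, 0.146, 0.158, 0.141, 0.89, -11.3, 0.228, 0.190, 0.83, -16.7),
    ("Chest", 0.105, 0.104, -0.6, 0.152, 0.160, 0.141, 0.88, -11.8, 0.262, 0.216, 0.82, -17.7),
    ("Head", 0.174, 0.184, 5.9, 0.144, 0.208, 0.208, 1.00, 0.1, 0.198, 0.193, 0.98, -2.2),
]

#: Corrected total evaporative resistance (m2Pa/W): textile skin, SC, CP.
#: Rows are ordered by the published sorting (magnitude of the textile-skin
#: correction).
_TABLE3_COLUMNS = ["label", "TS_R_et", "SC_R_et", "CP_R_et"]
_TABLE3_ROWS = [
    ("R.Hand", 4.6, 6.0, 446.6),
    ("Hands", 5.8, 9.2, 305.3),
    ("L.Lower leg", 7.8, 32.6, 132.4),
    ("Legs", 7.8, 28.1, 65.7),
    ("Thighs", 7.4, 27.7, 56.7),
    ("L.Hand", 7.7, 16.1, 245.8),
    ("Lower Arms", 8.1, 14.7, 87.0),
    ("Belly", 6.9, 43.7, 585.3),
    ("Lower legs", 9.1, 29.4, 99.5),
    ("Total", 8.2, 20.9, 81.0),
    ("Head, hands & feet excluded", 8.3, 21.2, 92.2),
    ("Hands & feet excluded", 8.4, 20.6, 73.7),
    ("Hands excluded", 8.4, 22.2, 78.1),
    ("Feet", 7.4, 65.6, 188.8),
    ("Arms", 8.7, 18.4, 73.9),
    ("R.Lower leg", 10.3, 26.3, 66.5),
    ("Torso", 8.7, 18.2, 180.9),
    ("Back", 9.0, 13.8, 165.1),
    ("Upper arms", 9.1, 21.2, 70.4),
    ("Buttocks", 9.2, 32.3, 98.6),
    ("Chest", 9.2, 14.6, 203.1),
    ("Head", 9.9, 16.0, 20.4),
]

#: Other published whole-garment constants.
_GARMENT = {
    "sc": {"f_cl": 1.26, "r_ecl": 13.2, "i_cl_si": 0.107, "mass_kg": 2.8},
    "cp": {"f_cl": 1.41, "r_ecl": 74.0, "i_cl_si": 0.177, "mass_kg": 4.1},
}

FIXTURE_NAMES = ("table1_sc", "table1_cp", "table2", "table3")


def load_fixture(name: str) -> Any:
    """Return a stored reference table.

    ``table1_sc``/``table1_cp`` give a dict of PHS model inputs; ``table2``
    and ``table3`` give DataFrames indexed by body-part label.
    """
    if name == "table1_sc":
        return dict(_TABLE1["sc"])
    if name == "table1_cp":
        return dict(_TABLE1["cp"])
    if name == "table2":
        return pd.DataFrame(_TABLE2_ROWS, columns=_TABLE2_COLUMNS).set_index(
            "label"
        )
    if name == "table3":
        return pd.DataFrame(_TABLE3_ROWS, columns=_TABLE3_COLUMNS).set_index(
            "label"
        )
    raise KeyError(
        f"unknown fixture {name!r}; available: {FIXTURE_NAMES}"
    )


def ensemble_properties(key: str) -> EnsembleProperties:
    """Packaged ensemble constants for ``"sc"`` or ``"cp"``.

    Whole-body totals come from the stored insulation/evaporative-resistance
    tables; the basic insulation and intrinsic evaporative resistance are the
    published values (derived by the laboratory with its own boundary-layer
    bookkeeping, see docs/methods.md).
    """
    key = key.lower()
    if key not in _GARMENT:
        raise KeyError(f"unknown ensemble {key!r}; available: ('sc', 'cp')")
    t1 = _TABLE1[key]
    t2 = load_fixture("table2")
    t3 = load_fixture("table3")
    col = key.upper()
    return EnsembleProperties(
        name=t1["name"],
        f_cl=_GARMENT[key]["f_cl"],
        i_t=float(t2.loc["Total", f"{col}_I_T"]),
        i_tr=float(t2.loc["Total", f"{col}_I_Tr"]),
        i_cl=clo_to_si(t1["i_cl_clo"]),
        r_et=float(t3.loc["Total", f"{col}_R_et"]),
        r_ecl=_GARMENT[key]["r_ecl"],
        i_m=t1["i_m"],
        mass=_GARMENT[key]["mass_kg"],
    )
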
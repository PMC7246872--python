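"""Predicted heat strain (PHS) simulation, ISO 7933:2004.

The PHS model is a minute-stepped whole-body heat-balance simulation
(Malchaire et al., Ann. Occup. Hyg. 45:123-135, 2001).  Each minute it
evaluates respiratory heat losses, dry convective/radiative exchange through
dynamically corrected clothing, the required evaporation ``E_req``, the
maximum achievable evaporation ``E_max``, required wettedness and evaporative
efficiency, and a first-order-lagged predicted sweat rate capped at ``SW_max``.
The resulting heat storage drives rectal temperature through a core/skin
two-node bookkeeping.  Two duration-limited-exposure (DLE) criteria are
tracked: rectal temperature reaching 38 degC and cumulative water loss
reaching a fraction of body mass (5% by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

from . import constants as c

__all__ = [
    "PHSInputs",
    "PHSState",
    "PHSResult",
    "DynamicClothing",
    "dubois_area",
    "saturation_vp",
    "dynamic_clothing_correction",
    "initial_state",
    "phs_step",
    "run_phs",
]

POSTURES = tuple(c.RADIATING_AREA_FRACTION)


class PHSValidationError(ValueError):
    pass


class PHSSimulationError(RuntimeError):
    """Raised when the minute update produces a non-finite quantity."""


def dubois_area(mass: float, height: float) -> float:
    """DuBois body surface area, m2, from mass (kg) and height (m)."""
    if mass <= 0 or height <= 0:
        raise PHSValidationError(
            f"mass and height must be > 0, got ({mass}, {height})"
        )
    return c.DUBOIS_K * mass**c.DUBOIS_MASS_EXP * height**c.DUBOIS_HEIGHT_EXP


def saturation_vp(t: float) -> float:
    """Saturation water vapour pressure over water, kPa (Magnus form)."""
    if not c.MAGNUS_T_MIN <= t <= c.MAGNUS_T_MAX:
        raise PHSValidationError(
            f"temperature {t} degC outside the Magnus fit range "
            f"[{c.MAGNUS_T_MIN}, {c.MAGNUS_T_MAX}]"
        )
    return c.MAGNUS_A * math.exp(c.MAGNUS_B * t / (t + c.MAGNUS_C))


# --- inputs -----------------------------------------------------------------


@dataclass(frozen=True)
class PHSInputs:
    """Configuration of one PHS run.

    ``m_watts`` and ``w_mech_watts`` are whole-body rates in W (converted
    internally to W/m2 of DuBois area).  ``i_cl_static`` is the *static*
    basic clothing insulation in clo and ``i_m_static`` the static moisture
    permeability index; the engine applies its own dynamic (wind + walking)
    corrections.  ``v_walk=None`` lets the model deduce a walking speed from
    the metabolic rate; ``walk_angle_deg=None`` selects the
    unknown-wind-direction branch.
    """

    t_a: float
    t_r: float
    p_a: float
    v_a: float
    m_watts: float
    i_cl_static: float
    i_m_static: float
    w_mech_watts: float = 0.0
    mass: float = 70.0
    height: float = 1.75
    body_surface_area: Optional[float] = None
    posture: str = "standing"
    acclimatized: bool = True
    drink_free: bool = True
    reflective_fraction: float = 0.0
    reflective_emissivity: float = 0.42
    v_walk: Optional[float] = 0.0
    walk_angle_deg: Optional[float] = None
    duration: int = 480
    water_loss_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mass <= 0 or self.height <= 0:
            raise PHSValidationError("mass and height must be > 0")
        if not 0 < self.i_m_static <= 1:
            raise PHSValidationError(
                f"i_m_static must lie in (0, 1], got {self.i_m_static}"
            )
        if self.i_cl_static < 0:
            raise PHSValidationError("i_cl_static cannot be negative")
        if not self.m_watts > self.w_mech_watts >= 0:
            raise PHSValidationError(
                "need metabolic rate > mechanical power >= 0, got "
                f"M={self.m_watts}, W={self.w_mech_watts}"
            )
        if self.duration < 1:
            raise PHSValidationError("duration must be >= 1 minute")
        if self.posture not in POSTURES:
            raise PHSValidationError(
                f"posture must be one of {POSTURES}, got {self.posture!r}"
            )
        if not 0 <= self.reflective_fraction <= 1:
            raise PHSValidationError("reflective_fraction must lie in [0, 1]")
        if self.v_a < 0 or (self.v_walk is not None and self.v_walk < 0):
            raise PHSValidationError("velocities cannot be negative")
        if self.p_a < 0:
            raise PHSValidationError("vapour pressure cannot be negative")

    @property
    def a_dubois(self) -> float:
        if self.body_surface_area is not None:
            return self.body_surface_area
        return dubois_area(self.mass, self.height)

    @property
    def met(self) -> float:
        """Metabolic rate per unit body surface, W/m2."""
        return self.m_watts / self.a_dubois

    @property
    def d_max_g(self) -> float:
        """Water-loss limit in grams."""
        frac = self.water_loss_fraction
        if frac is None:
            frac = (
                c.WATER_LOSS_FRACTION_DEFAULT
                if self.drink_free
                else c.WATER_LOSS_FRACTION_NO_DRINK
            )
        return frac * self.mass * 1000.0


# --- dynamic clothing correction --------------------------------------------


@dataclass(frozen=True)
class DynamicClothing:
    """Wind- and walking-corrected clothing parameters (ISO 7933:2004, 7.2)."""

    f_cl: float
    v_r: float
    v_walk: float
    i_tot_static: float
    i_tot_dyn: float
    i_a_dyn: float
    i_cl_dyn: float
    i_m_dyn: float
    r_t_dyn: float


def _relative_velocity(
    v_a: float,
    v_walk: Optional[float],
    met: float,
    walk_angle_deg: Optional[float],
) -> tuple[float, float]:
    """Relative air velocity and effective walking speed."""
    if v_walk is None:
        # walking speed deduced from the metabolic rate
        v_walk = c.V_WALK_FROM_MET_SLOPE * (met - c.V_WALK_FROM_MET_OFFSET)
        v_walk = min(max(v_walk, 0.0), c.V_WALK_FROM_MET_CAP)
        v_r = v_a
    elif walk_angle_deg is not None:
        v_r = abs(v_a - v_walk * math.cos(math.radians(walk_angle_deg)))
    else:
        v_r = max(v_a, v_walk)
    return max(v_r, c.V_REL_FLOOR), v_walk


def dynamic_clothing_correction(
    i_cl_static: float,
    i_m_static: float,
    v_a: float,
    v_walk: Optional[float] = 0.0,
    met: float = 100.0,
    walk_angle_deg: Optional[float] = None,
) -> DynamicClothing:
    """Dynamic total insulation and evaporative resistance.

    ``i_cl_static`` in clo, ``met`` in W/m2 (used only when ``v_walk`` is
    None).  Applies the standard's relative-air-velocity and walking-speed
    reduction factors to the static total insulation, the boundary air layer
    and the permeability index, then derives the dynamic total evaporative
    resistance via the Lewis relation.
    """
    if i_cl_static < 0 or not 0 < i_m_static <= 1:
        raise PHSValidationError(
            f"need i_cl_static >= 0 and i_m_static in (0, 1], got "
            f"({i_cl_static}, {i_m_static})"
        )
    v_r, v_walk = _relative_velocity(v_a, v_walk, met, walk_angle_deg)

    f_cl = 1.0 + c.PHS_FCL_SLOPE_PER_CLO * i_cl_static
    i_cl_si = i_cl_static * c.CLO_TO_SI
    i_tot_static = i_cl_si + c.PHS_I_A_STATIC / f_cl

    v_ux = min(v_r, c.V_REL_CAP)
    w_ux = min(v_walk, c.V_WALK_CAP)
    corr_cl = 1.044 * math.exp(
        (0.066 * v_ux - 0.398) * v_ux + (0.094 * w_ux - 0.378) * w_ux
    )
    corr_cl = min(corr_cl, 1.0)
    corr_ia = math.exp(
        (0.047 * v_ux - 0.472) * v_ux + (0.117 * w_ux - 0.342) * w_ux
    )
    corr_ia = min(corr_ia, 1.0)
    # blend between the nude and the fully-clothed correction below 0.6 clo
    if i_cl_static <= 0.6:
        corr_tot = (
            (0.6 - i_cl_static) * corr_ia + i_cl_static * corr_cl
        ) / 0.6
    else:
        corr_tot = corr_cl

    i_tot_dyn = i_tot_static * corr_tot
    i_a_dyn = corr_ia * c.PHS_I_A_STATIC
    i_cl_dyn = max(i_tot_dyn - i_a_dyn / f_cl, 1e-6)

    corr_e = (2.6 * corr_tot - 6.5) * corr_tot + 4.9
    i_m_dyn = min(i_m_static * corr_e, c.I_M_DYN_CAP)
    r_t_dyn = i_tot_dyn / i_m_dyn / c.LEWIS_PHS

    return DynamicClothing(
        f_cl=f_cl,
        v_r=v_r,
        v_walk=v_walk,
        i_tot_static=i_tot_static,
        i_tot_dyn=i_tot_dyn,
        i_a_dyn=i_a_dyn,
        i_cl_dyn=i_cl_dyn,
        i_m_dyn=i_m_dyn,
        r_t_dyn=r_t_dyn,
    )


def sweat_rate_max(met: float, a_dubois: float, acclimatized: bool) -> float:
    """Maximum sweat rate cap, in the standard's internal W/m2 convention."""
    sw_max = (met - 32.0) * a_dubois
    sw_max = min(max(sw_max, c.SW_MAX_FLOOR), c.SW_MAX_CEIL)
    if acclimatized:
        sw_max *= c.SW_MAX_ACCLIMATIZATION_FACTOR
    return sw_max


# --- state ------------------------------------------------------------------


@dataclass(frozen=True)
class PHSState:
    """State of the simulation after ``minute`` minutes of exposure."""

    minute: int
    t_re: float
    t_sk: float
    t_cr: float
    t_cr_eq: float
    skin_core_weight: float
    sweat_rate: float  # W/m2
    water_loss_g: float
    e_req: float = 0.0
    e_max: float = 0.0
    e_p: float = 0.0
    wettedness: float = 0.0

    def sweat_rate_gph(self, a_dubois: float) -> float:
        """Sweat rate in g/h for a given body surface area."""
        return self.sweat_rate * c.SWEAT_G_CONVERSION * a_dubois * 60.0


def initial_state() -> PHSState:
    """Standard initial conditions: thermoneutral core, 34.1 degC skin."""
    return PHSState(
        minute=0,
        t_re=c.T_CORE_INITIAL,
        t_sk=c.T_SKIN_INITIAL,
        t_cr=c.T_CORE_INITIAL,
        t_cr_eq=c.T_CORE_INITIAL,
        skin_core_weight=c.SKIN_CORE_WEIGHT_INITIAL,
        sweat_rate=0.0,
        water_loss_g=0.0,
    )


def phs_step(state: PHSState, inputs: PHSInputs) -> PHSState:
    """Advance the simulation by one minute.

    Deterministic: identical (state, inputs) give an identical next state.
    """
    adu = inputs.a_dubois
    met = inputs.met
    wme = inputs.w_mech_watts / adu
    ta, tr, pa, va = inputs.t_a, inputs.t_r, inputs.p_a, inputs.v_a
    sp_heat = c.BODY_SPECIFIC_HEAT_COEF * inputs.mass / adu
    dyn = dynamic_clothing_correction(
        inputs.i_cl_static,
        inputs.i_m_static,
        va,
        inputs.v_walk,
        met,
        inputs.walk_angle_deg,
    )
    sw_max = sweat_rate_max(met, adu, inputs.acclimatized)
    w_max = (
        c.W_MAX_ACCLIMATIZED
        if inputs.acclimatized
        else c.W_MAX_NON_ACCLIMATIZED
    )
    const_teq = math.exp(-1.0 / c.TIME_CONSTANT_CORE_EQ_MIN)
    const_tsk = math.exp(-1.0 / c.TIME_CONSTANT_SKIN_MIN)
    const_sw = math.exp(-1.0 / c.TIME_CONSTANT_SWEAT_MIN)

    tsk0, tcr0, tre0 = state.t_sk, state.t_cr, state.t_re
    tcreq0, wg0, sw0 = state.t_cr_eq, state.skin_core_weight, state.sweat_rate

    # equilibrium core temperature tied to the metabolic rate, 10 min lag
    tcreq_m = 0.0036 * met + 36.6
    tcreq = tcreq0 * const_teq + tcreq_m * (1.0 - const_teq)
    dstor_eq = sp_heat * (tcreq - tcreq0) * (1.0 - wg0)

    # equilibrium skin temperature: nude / clothed regressions, 3 min lag
    tsk_eq_cl = (
        12.165 + 0.02017 * ta + 0.04361 * tr + 0.19354 * pa
        - 0.25315 * va + 0.005346 * met + 0.51274 * tre0
    )
    tsk_eq_nu = (
        7.191 + 0.064 * ta + 0.061 * tr + 0.198 * pa - 0.348 * va
        + 0.616 * tre0
    )
    clo = inputs.i_cl_static
    if clo >= 0.6:
        tsk_eq = tsk_eq_cl
    elif clo <= 0.2:
        tsk_eq = tsk_eq_nu
    else:
        tsk_eq = tsk_eq_nu + 2.5 * (tsk_eq_cl - tsk_eq_nu) * (clo - 0.2)
    tsk = tsk0 * const_tsk + tsk_eq * (1.0 - const_tsk)
    p_sk = saturation_vp(tsk)

    # dry heat exchange through the clothing: convection coefficient is the
    # larger of natural and forced; clothing surface temperature by iteration
    z = 3.5 + 5.2 * dyn.v_r if dyn.v_r <= 1.0 else 8.7 * dyn.v_r**0.6
    hc_dyn = max(2.38 * abs(tsk - ta) ** 0.25, z)
    aux_r = c.STEFAN_BOLTZMANN * c.RADIATING_AREA_FRACTION[inputs.posture]
    f_cl_r = (
        (1.0 - inputs.reflective_fraction) * c.EMISSIVITY_CLOTHING
        + inputs.reflective_fraction * inputs.reflective_emissivity
    )
    tcl = tr + 0.1
    while True:
        h_r = (
            f_cl_r
            * aux_r
            * ((tcl + 273.0) ** 4 - (tr + 273.0) ** 4)
            / (tcl - tr)
        )
        tcl_new = (
            dyn.f_cl * (hc_dyn * ta + h_r * tr) + tsk / dyn.i_cl_dyn
        ) / (dyn.f_cl * (hc_dyn + h_r) + 1.0 / dyn.i_cl_dyn)
        if abs(tcl - tcl_new) <= c.FIXED_POINT_TOL:
            break
        tcl = (tcl + tcl_new) / 2.0
    conv = dyn.f_cl * hc_dyn * (tcl - ta)
    rad = dyn.f_cl * h_r * (tcl - tr)

    # respiratory losses
    t_exp = 28.56 + 0.115 * ta + 0.641 * pa
    c_res = 0.001516 * met * (t_exp - ta)
    e_res = 0.00127 * met * (59.34 + 0.53 * ta - 11.63 * pa)

    e_max = (p_sk - pa) / dyn.r_t_dyn
    e_req = met - dstor_eq - wme - c_res - e_res - conv - rad

    # required sweat rate through required wettedness / evaporative efficiency
    if e_req <= 0.0:
        e_req = 0.0
        sw_req = 0.0
    elif e_max <= 0.0:
        e_max = 0.0
        sw_req = sw_max
    else:
        w_req = e_req / e_max
        if w_req >= 1.7:
            sw_req = sw_max
        else:
            eff = 1.0 - w_req**2 / 2.0 if w_req <= 1.0 else (2.0 - w_req) ** 2 / 2.0
            sw_req = min(e_req / eff, sw_max)

    # predicted sweat rate, 10 min lag, then predicted evaporation
    sw_p = sw0 * const_sw + sw_req * (1.0 - const_sw)
    if sw_p <= 0.0:
        sw_p = 0.0
        wp = 0.0
        e_p = 0.0
    else:
        k = e_max / sw_p
        wp = 1.0
        if k >= 0.5:
            wp = -k + math.sqrt(k * k + 2.0)
        wp = min(wp, w_max)
        e_p = wp * e_max

    # heat storage and core temperature (fixed point on the skin/core weight)
    d_storage = e_req - e_p + dstor_eq
    tcr1 = tcr0
    while True:
        wg = 0.3 - 0.09 * (tcr1 - 36.8)
        wg = min(max(wg, c.SKIN_CORE_WEIGHT_MIN), c.SKIN_CORE_WEIGHT_MAX)
        tcr = d_storage / sp_heat + tsk0 * wg0 / 2.0 - tsk * wg / 2.0
        tcr = (tcr + tcr0 * (1.0 - wg0 / 2.0)) / (1.0 - wg / 2.0)
        if abs(tcr - tcr1) <= c.FIXED_POINT_TOL:
            break
        tcr1 = (tcr1 + tcr) / 2.0

    tre = tre0 + (2.0 * tcr - 1.962 * tre0 - 1.31) / 9.0
    water = state.water_loss_g + (sw_p + e_res) * c.SWEAT_G_CONVERSION * adu

    new = PHSState(
        minute=state.minute + 1,
        t_re=tre,
        t_sk=tsk,
        t_cr=tcr,
        t_cr_eq=tcreq,
        skin_core_weight=wg,
        sweat_rate=sw_p,
        water_loss_g=water,
        e_req=e_req,
        e_max=e_max,
        e_p=e_p,
        wettedness=wp,
    )
    for name in ("t_re", "t_sk", "t_cr", "sweat_rate", "water_loss_g"):
        if not math.isfinite(getattr(new, name)):
            raise PHSSimulationError(
                f"non-finite {name} at minute {new.minute}"
            )
    return new


# --- full run ---------------------------------------------------------------


@dataclass(frozen=True)
class PHSResult:
    """Outcome of one PHS run.

    ``dle_tre`` and ``dle_water`` are the first minutes at which rectal
    temperature reaches 38 degC and cumulative water loss reaches the body-
    mass-fraction limit; both equal ``duration`` when never crossed.
    """

    dle_tre: int
    dle_water: int
    final_water_loss_g: float
    final_t_re: float
    duration: int
    trajectory: tuple[PHSState, ...] = field(repr=False)

    @property
    def dle_operative(self) -> int:
        """The binding limit: min of the two criteria."""
        return min(self.dle_tre, self.dle_water)

    @property
    def tre_limited(self) -> bool:
        return self.dle_tre < self.duration

    @property
    def water_limited(self) -> bool:
        return self.dle_water < self.duration

    def trajectory_frame(self):
        """Minute-by-minute trajectory as a pandas DataFrame."""
        import pandas as pd

        return pd.DataFrame(
            {
                "minute": [s.minute for s in self.trajectory],
                "t_re_C": [s.t_re for s in self.trajectory],
                "t_sk_C": [s.t_sk for s in self.trajectory],
                "sweat_rate_Wm2": [s.sweat_rate for s in self.trajectory],
                "water_loss_g": [s.water_loss_g for s in self.trajectory],
                "E_req_Wm2": [s.e_req for s in self.trajectory],
                "E_max_Wm2": [s.e_max for s in self.trajectory],
                "E_p_Wm2": [s.e_p for s in self.trajectory],
                "wettedness": [s.wettedness for s in self.trajectory],
            }
        )


def run_phs(inputs: PHSInputs) -> PHSResult:
    """Run the minute-stepped simulation for ``inputs.duration`` minutes."""
    state = initial_state()
    trajectory = [state]
    dle_tre = dle_water = 0
    d_max = inputs.d_max_g
    for _ in range(inputs.duration):
        state = phs_step(state, inputs)
        trajectory.append(state)
        if dle_tre == 0 and state.t_re >= c.T_RECTAL_LIMIT:
            dle_tre = state.minute
        if dle_water == 0 and state.water_loss_g >= d_max:
            dle_water = state.minute
    return PHSResult(
        dle_tre=dle_tre or inputs.duration,
        dle_water=dle_water or inputs.duration,
        final_water_loss_g=state.water_loss_g,
        final_t_re=state.t_re,
        duration=inputs.duration,
        trajectory=tuple(trajectory),
    )
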
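"""Physical constants used across the package.

Every constant that enters a computation lives here so that a reader can audit
the provenance of each number in one place.  The predicted-heat-strain (PHS)
constants follow the program published with ISO 7933:2004 (the model of
Malchaire et al., Ann. Occup. Hyg. 45:123-135, 2001); clothing-lab constants
follow ISO 9920 / ISO 15831 / ASTM F2370 conventions.
"""

# --- unit conversions -------------------------------------------------------

#: 1 clo in m2K/W (ISO 9920).
CLO_TO_SI = 0.155

#: Lewis relation used for the static moisture permeability index, K/kPa.
#: i_m = (I_T / R_et) / (LEWIS_MANIKIN / 1000)  with R_et in m2Pa/W.
LEWIS_MANIKIN = 16.65

#: Lewis relation used inside the PHS engine to derive the dynamic total
#: evaporative resistance from the dynamic insulation and permeability index
#: (ISO 7933:2004, eq. for R_T,dyn).
LEWIS_PHS = 16.7

# --- saturation vapour pressure (Magnus form, over water) -------------------

#: p_sat(t) = MAGNUS_A * exp(MAGNUS_B * t / (t + MAGNUS_C))  [kPa], t in degC.
MAGNUS_A = 0.6105
MAGNUS_B = 17.27
MAGNUS_C = 237.3

#: validity range for the Magnus fit, degC
MAGNUS_T_MIN = -40.0
MAGNUS_T_MAX = 100.0

# --- DuBois body surface area ----------------------------------------------

#: A_Du = DUBOIS_K * mass^DUBOIS_MASS_EXP * height^DUBOIS_HEIGHT_EXP
#: mass in kg, height in m, area in m2 (DuBois & DuBois 1916; ISO 7933 input).
DUBOIS_K = 0.202
DUBOIS_MASS_EXP = 0.425
DUBOIS_HEIGHT_EXP = 0.725

# --- black-globe / mean radiant temperature (ISO 7726, 150 mm globe) --------

#: forced-convection coefficient of the standard 150 mm matte-black globe:
#: t_r = ((t_g+273)^4 + GLOBE_FORCED_COEF * v_a^GLOBE_V_EXP * (t_g - t_a))^0.25 - 273
GLOBE_FORCED_COEF = 2.5e8
GLOBE_V_EXP = 0.6

# --- outdoor WBGT weights (ISO 7243) ----------------------------------------

WBGT_W_NATURAL_WET_BULB = 0.7
WBGT_W_GLOBE = 0.2
WBGT_W_AIR = 0.1

# --- PHS engine (ISO 7933:2004 program) -------------------------------------

#: static boundary-air-layer insulation in quiet air, m2K/W (7.2 in standard).
PHS_I_A_STATIC = 0.111

#: clothing area factor model: f_cl = 1 + 0.3 * I_cl[clo]  (7.2 in standard).
PHS_FCL_SLOPE_PER_CLO = 0.3

#: Stefan-Boltzmann constant, W/m2K4.
STEFAN_BOLTZMANN = 5.67e-8

#: effective radiating area fraction A_r/A_Du by posture (7.3 in standard).
RADIATING_AREA_FRACTION = {"sitting": 0.70, "standing": 0.77, "crouching": 0.67}

#: emissivity of ordinary (non-reflective) clothing.
EMISSIVITY_CLOTHING = 0.97

#: exponential-averaging constants: time constants of 10 min (equilibrium core
#: temperature, sweat rate) and 3 min (skin temperature) at a 1 min step
#: (8.2, 8.4 in standard).
TIME_CONSTANT_CORE_EQ_MIN = 10.0
TIME_CONSTANT_SKIN_MIN = 3.0
TIME_CONSTANT_SWEAT_MIN = 10.0

#: body specific heat parameter: sp_heat = 57.83 * mass / A_Du  [W·min/(m2·K)]
#: (heat storage bookkeeping, 8.6 in standard).
BODY_SPECIFIC_HEAT_COEF = 57.83

#: initial physiological state (8.1 in standard).
T_CORE_INITIAL = 36.8
T_SKIN_INITIAL = 34.1
SKIN_CORE_WEIGHT_INITIAL = 0.3

#: skin/core weighting bounds: w = 0.3 - 0.09*(t_cr - 36.8), clipped (8.6).
SKIN_CORE_WEIGHT_MAX = 0.3
SKIN_CORE_WEIGHT_MIN = 0.1

#: maximum skin wettedness (8.5): 0.85 non-acclimatised, 1.0 acclimatised.
W_MAX_NON_ACCLIMATIZED = 0.85
W_MAX_ACCLIMATIZED = 1.0

#: maximum sweat rate (8.5): (M/A_Du - 32)*A_Du clamped to [250, 400], times
#: 1.25 when acclimatised; the standard's program uses the result directly in
#: W/m2 against the required sweat rate.
SW_MAX_FLOOR = 250.0
SW_MAX_CEIL = 400.0
SW_MAX_ACCLIMATIZATION_FACTOR = 1.25

#: water-loss limits as fraction of body mass: 5% (95th-percentile protection,
#: used throughout here), 7.5% (average subject) and 3% when drinking is
#: restricted (4.2 in standard).
WATER_LOSS_FRACTION_DEFAULT = 0.05
WATER_LOSS_FRACTION_AVERAGE = 0.075
WATER_LOSS_FRACTION_NO_DRINK = 0.03

#: rectal-temperature DLE criterion, degC.
T_RECTAL_LIMIT = 38.0

#: conversion of an evaporative heat flow summed over minutes (W/m2 · min) to
#: grams of water: g = sum * SWEAT_G_CONVERSION * A_Du  (2454 J/g latent heat;
#: the standard's program writes the factor as 2.67/1.8/60 per m2 of a
#: reference 1.8 m2 body).
SWEAT_G_CONVERSION = 2.67 / 1.8 / 60.0

#: relative air velocity handling (7.2): floor for the correction equations'
#: stated validity, caps used inside the reduction factors.
V_REL_FLOOR = 0.15
V_REL_CAP = 3.0
V_WALK_CAP = 1.5

#: walking speed deduced from metabolic rate when unspecified (7.2):
#: v_w = 0.0052*(M/A_Du - 58), capped at 0.7 m/s.
V_WALK_FROM_MET_SLOPE = 0.0052
V_WALK_FROM_MET_OFFSET = 58.0
V_WALK_FROM_MET_CAP = 0.7

#: dynamic permeability index cap (7.2).
I_M_DYN_CAP = 0.9

#: convergence tolerance for the clothing-surface-temperature and core-
#: temperature fixed-point iterations, degC.
FIXED_POINT_TOL = 1e-3
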
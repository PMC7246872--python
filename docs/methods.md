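# Methods

This note documents the models implemented in `heatstrain`, the constants
and defaults they use, what the synthetic generators emulate, and the design
choices made where conventions genuinely diverge.

## Zone calculus and aggregation

A heated thermal manikin measures, zone by zone, the areal heat loss `q`
(W/m²) needed to hold its surface at `t_sf` against ambient `t_a`; the zone's
total thermal insulation is `I = (t_sf − t_a)/q` (m²K/W).  Insulation tests
assume a positive gradient and positive heat loss; records violating either
are rejected with the zone named.

Two aggregation conventions exist and both are provided:

* **parallel** (default): `I = ΣAᵢ / Σ(Aᵢ/Iᵢ)`, the area-weighted harmonic
  mean.  It is exactly equivalent to summing the zone heat flows at a common
  temperature gradient and is the whole-body convention of ISO 15831.
* **serial**: `I = Σ(AᵢIᵢ)/ΣAᵢ`, the area-weighted arithmetic mean.

Parallel never exceeds serial (harmonic ≤ arithmetic mean), with equality
iff all zone insulations agree; both are invariant to zone order and to
splitting a zone into sub-zones of equal insulation.  Replicates (two per
condition by laboratory convention) are arithmetically averaged *before*
aggregation, so duplicating every record is a no-op.

Zone surface areas for the packaged 17-zone male-shaped manikin are
**documented approximations** totalling ≈1.77 m² (the instrument's true zone
areas are not public); they are fully configurable via a YAML table.  For
this reason the stored whole-body reference totals are treated as measured
fixture data, not as values the default area table must reproduce.
Exclusion totals ("Head, hands & feet excluded" and similar) aggregate the
complement zone set with its own areas.

Static/dynamic comparison reports the resultant-to-static ratio `I_Tr/I_T`
and the percentage change; report rounding follows the laboratory
convention (insulation 3 dp, ratio 2 dp, percent 1 dp).  Published report
tables carry percentages computed from unrounded laboratory values, so
recomputing them from the printed 3-dp entries can differ by up to ~0.5
percentage points; the package always computes from the precision it is
given and makes no attempt to reverse-engineer laboratory rounding.

## Garment-level properties

* **Clothing area factor**: `f_cl = (A_cl,front + A_cl,side)/(A_nu,front +
  A_nu,side)` from projected photographs, floored at 1.0 (a garment cannot
  shrink the radiating surface) with a warning.
* **Basic insulation**: `I_cl = I_T − I_a/f_cl` with `I_a` the measured nude
  boundary-air-layer insulation.
* **Evaporative resistance (heat-loss method)**: at isothermal settings
  (manikin surface = air = 34 °C) the sweating manikin's heat loss is purely
  evaporative, so `R_et = (p_sat(t_eval) − p_a)·1000/q_evap` (m²Pa/W).  The
  evaluation temperature is either the 34 °C set-point or, with the
  wet-skin correction selected, the measured wet-textile-skin temperature —
  evaporative cooling depresses the wet skin below the set-point, lowering
  the true driving pressure and hence the corrected resistance.  The exact
  correction coefficients used by the originating laboratory are not
  public, so the correction is parameterised by the wet-skin temperature
  itself and the packaged reference tables store corrected values directly.
* **Moisture permeability index**: `i_m = (I_T/R_et)/0.01665`, Lewis
  relation 16.65 K/kPa, clipped to (0, 1].  This constant reproduces the
  published indices (0.55 and 0.19) exactly from the stored whole-body
  totals.
* **Intrinsic evaporative resistance**: `R_ecl = R_et − R_e,bnd/f_cl`, the
  boundary term defaulting to the measured wet-textile-skin total
  (8.2 m²Pa/W).  Note that the published intrinsic values for the two
  reference ensembles (13.2 and 74 m²Pa/W) embed the laboratory's own
  boundary bookkeeping and are *not* exactly recovered by this arithmetic
  (which gives 14.4 and 75.2); the packaged ensembles therefore store the
  published values verbatim rather than forcing agreement.  The same applies
  to the published basic insulations (0.107/0.177 m²K/W vs 0.113 m²K/W
  recomputed for the lighter ensemble from the printed totals).
* Air-velocity differences between the insulation (0.21 m/s) and
  evaporative-resistance (0.54 m/s) test protocols are metadata only; no
  cross-correction is attempted.

## The PHS engine

The predicted-heat-strain model is the minute-stepped heat-balance
simulation of ISO 7933:2004 (Malchaire et al. 2001).  The equations and
every coefficient follow the standard's published program; all constants
are collected in `heatstrain/constants.py` with their role noted.  Per
minute, with all rates in W/m² of DuBois area:

1. equilibrium core temperature `t_cr,eq = 0.0036·M + 36.6` approached with
   a 10-min time constant; the associated storage debit uses the previous
   skin/core mass weighting;
2. equilibrium skin temperature from the standard's clothed and nude
   regressions (blended between 0.2 and 0.6 clo), approached with a 3-min
   time constant;
3. dynamic clothing: relative air velocity (walking-aware, capped at 3 m/s,
   floored at 0.15 m/s — the stated validity floor of the correction
   equations), reduction factors for the total insulation, the boundary
   layer and the permeability index (`i_m,dyn ≤ 0.9`), and the dynamic
   evaporative resistance via the standard's Lewis constant 16.7;
4. clothing surface temperature by damped fixed-point iteration of the
   radiative coefficient (tolerance 0.001 °C), giving convective and
   radiative flows; respiratory convective and evaporative losses from the
   standard's regressions;
5. `E_req` (residual of the balance) and `E_max = (p_sk − p_a)/R_T,dyn`;
   required wettedness `w_req = E_req/E_max` (capped 1.7), evaporative
   efficiency `1 − w²/2` (or `(2−w)²/2` above 1), required sweat rate
   `SW_req = E_req/η` capped at `SW_max`;
6. predicted sweat rate lagging `SW_req` with a 10-min time constant;
   predicted wettedness `w_p = −k + √(k²+2)` for `k = E_max/SW_p ≥ 0.5`,
   bounded by `w_max` (0.85 non-acclimatized, 1.0 acclimatized); predicted
   evaporation `E_p = w_p·E_max`;
7. storage `E_req − E_p + dS_eq` drives the core temperature through a
   fixed point on the core-temperature-dependent skin/core weighting
   (0.3 − 0.09·(t_cr − 36.8), clipped to [0.1, 0.3]); rectal temperature
   follows `t_re ← t_re + (2·t_cr − 1.962·t_re − 1.31)/9`;
8. water loss accumulates sweat plus respiratory evaporation, converted to
   grams with the 2454 J/g latent heat.

`SW_max = (M/A_Du − 32)·A_Du` clamped to [250, 400] and multiplied by 1.25
when acclimatized, compared against the required sweat rate in W/m² exactly
as in the standard's program.  Initial state is thermoneutral (`t_re = t_cr
= 36.8 °C`, `t_sk = 34.1 °C` for all postures; posture enters via the
effective radiating area fraction 0.70/0.77/0.67 for
sitting/standing/crouching).

**DLE criteria**: first minute with `t_re ≥ 38 °C`, and first minute with
cumulative water loss ≥ 5 % of body mass (3 % when drinking is restricted;
the fraction is configurable, with the 7.5 %-average-subject alternative
available as a constant).  Runs default to 480 min (8 h); a criterion never
crossed reports the full duration.  The operative limit is the minimum of
the two.  Metabolic and mechanical rates are accepted as whole-body watts
and divided by the DuBois area `0.202·m^0.425·h^0.725`; reading workloads
of 200–350 W as W/m² instead would roughly halve the water-loss DLE and is
not what the packaged configurations mean.

The model's own dynamic corrections expect *static* basic insulation (clo)
and *static* permeability index; manikin-dynamic (walking) values must not
be fed in, or motion would be double-counted.

Saturation vapour pressure uses the Magnus form
`0.6105·exp(17.27·t/(t+237.3))` kPa, valid −40…100 °C, shared by the skin,
ambient and garment calculations.

A deliberate consequence of the equations worth knowing: under a hot
radiant, high-humidity scenario the sweat rate sits at `SW_max` almost from
the start, so the water-loss DLE is nearly workload-independent wherever
the cap binds (the cap's lower clamp covers whole-body rates up to
~310 W for a 1.84 m² body), while the core-temperature DLE varies strongly
with air temperature and workload.  At mild cells of the scenario grid the
rectal temperature can equilibrate below 38 °C, leaving dehydration as the
binding limit there — the scenario tables report both criteria and their
minimum so this is always visible.

## Environmental preprocessing

* Mean radiant temperature from a standard 150 mm matte-black globe,
  forced-convection form `t_r = ((t_g+273)⁴ + 2.5·10⁸·v_a^0.6·(t_g −
  t_a))^0.25 − 273`; the packaged constants reproduce the field pairing
  (globe 44 °C, air 34 °C, wind 2 m/s → 70 °C) at the nearest degree.  When
  a record carries both a globe and a mean-radiant value the given `t_r`
  wins unless recomputation is requested.
* `p_a = RH/100 · p_sat(t_a)`; outdoor WBGT `0.7·t_nw + 0.2·t_g + 0.1·t_a`.
* The hour-by-hour driver runs one independent PHS simulation per (hour,
  workload) — no physiological carry-over between hours, so morning DLEs
  are optimistic and afternoon DLEs pessimistic relative to a continuous
  day.  Hour labels are opaque; no interpolation is performed.
* The scenario driver holds RH (default 70 %), `t_r` (70 °C) and wind
  (2 m/s) fixed while sweeping air temperature (default 28–36 °C) and
  workload, and reports both DLEs plus their minimum.

## Synthetic data

The zone generator inverts the insulation definition (`q = ΔT/I_true` at
the 34-over-20 °C laboratory gradient), applies multiplicative Gaussian
noise (truncated at 0.1 to keep heat losses positive) and emits two
replicates per condition; dynamic truths are static truths times per-zone
ratios shaped like a nude manikin's walking response (extremities reduced
most, head essentially unchanged).  Noise-free data invert to the
configured truths to machine precision, which is what the recovery tests
assert.

The weather generator is a clipped cosine with its minimum in the small
hours and peak at 14:00, hitting the configured extremes exactly; RH runs
in anti-phase (default 40–90 %), wind is constant, and a Stull (2011)
wet-bulb approximation provides `t_nw` for WBGT.  It emulates the *ranges
and shape* of a hot field day, not any particular day's trace: passing
tests demonstrate correct plumbing and the expected midday-severity
ordering, not agreement with a specific weather record.  Real days have
asymmetric heating, wind variation and humidity microstructure that the
sinusoid deliberately omits.

## Numerical choices and limitations

* Fixed 1-min step; both fixed-point iterations use a 0.001 °C tolerance
  with averaging damping, as in the standard's program.
* All simulations are deterministic; generators are pure functions of their
  spec (seed included).
* Tests sample the scenario grid at 2 °C steps with the three published
  workloads per ensemble (30 full-length runs) — dense 1 °C sweeps are the
  CLI default and behave identically.
* The PHS model is a population-average instrument: no female- or
  subgroup-specific recalibration, no repeated-day carry-over, and reduced
  reliability for heavily insulating encapsulating clothing.  Manikin
  hardware control, per-layer fabric resistances, mass-loss evaporative
  resistance and condensation are out of scope.
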
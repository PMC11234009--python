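# Methods

`coldwater` simulates the thermal response of an average human body immersed
in cold or lukewarm water (or forced air), predicts hypothermia survival
times and active-rewarming rates, and cross-checks the transient solver
against closed-form references.  This note records the model, its numerical
treatment, the calibration protocol, and the places where the design was
genuinely open.

## Governing model

Tissue temperature in every body segment obeys the Pennes bioheat equation
in 1-D radial form,

    ρ cp ∂T/∂t = (1/r^d) ∂/∂r ( r^d k ∂T/∂r )
                 + ρ_b c_b ω_b (T_b − T) + q_m + q_shiv + q_cal ,

with d = 1 for cylinders and d = 2 for the head sphere.  There is no
tissue-scale advection and no external volumetric source; all environmental
exchange enters through the Robin surface condition q₀ = h (T_ext − T),
where h is a lumped convective-plus-radiative coefficient held constant per
scenario (evaporation is taken as zero during immersion).

Segments do not conduct into one another.  They are coupled exclusively
through a lumped arterial blood pool (5 L, ρ_b = 1060 kg/m³,
c_b = 3800 J/(kg·°C)) whose energy balance collects every perfusion
exchange and the convected share of shivering heat:

    m_b c_b dT_b/dt = − Σ ρ_b c_b ω_b (T_b − T) V_cell + λ Q_shiv .

### Body geometry

Fifteen-ish segments: a spherical head, a neck cylinder, three trunk
cylinders (chest, back, abdomen — each internal-organ core → muscle →
4 mm skin), and paired arms, hands, thighs, legs, feet (muscle → skin).
Only aggregate anthropometry is constrained: a uniform radial and a uniform
axial scale factor are solved (scipy `fsolve`) so the assembly reproduces
BSA = 1.7 m² and volume = 0.057 m³ exactly; mass follows as
volume × 1060 kg/m³ ≈ 60.4 kg.  The internal-organ core occupies 60 % of
the trunk radius (≈ 10 kg of organ tissue — a physiologic organ mass; the
value is configurable).  Tissue parameters are the four-compartment set
(muscle, skin, head, internal organs) bundled in `coldwater.tissues`.

The rectal (core) temperature is the innermost node of the abdominal
segment; its tissue is strongly perfused, so it tracks the blood pool with
a ~13 min time constant, which is what a rectal probe does.

Mean skin temperature is the nine-region weighted sum
(0.12 back + 0.12 chest + 0.12 abdomen + 0.14 arm + 0.19 thigh + 0.13 leg
+ 0.05 hand + 0.07 head + 0.06 foot); paired limbs report their (by
symmetry identical) surface temperature.

### Basal-offset (calibrated basal state)

The initial condition is normothermic: interior 37 °C, skin 34.5 °C,
blood 37 °C.  At assembly a constant per-cell source q_cal is fixed that
cancels, node by node, the basal perfusion exchange at the initial
temperatures plus the basal metabolic heat.  It represents the basal losses
(respiration, evaporation, basal vasomotor tone) that the immersion
boundary condition does not model, and makes the initial state a
metabolic/perfusion equilibrium so that *deviations* from the basal state
drive the dynamics.  Consequence: in a thermoneutral 37 °C bath the core
and blood hold 37 °C to within ~0.1 °C indefinitely, while the skin trace
necessarily relaxes from 34.5 °C toward the bath (a surface at 34.5 °C with a
37 °C environment cannot be stationary for arbitrary h).  For raw-Pennes
verification against closed forms the offset is disabled
(`basal_offset=False`).

## Thermoregulation

Linear-gain laws around the set-points Tc_set = 37 °C, Ts_set = 34.5 °C.

**Vasomotor control.**  Skin perfusion factor
f = clamp(1 − a_s (Ts_set − Ts), f_min, 1) on the cold side
(a_s = 0.2 /°C, f_min = 0.1) and f = clamp(1 + a_d (Ts − Ts_set), 1, f_max)
on the warm side (a_d = 1.5 /°C, f_max = 12): cold-induced cutaneous
vasoconstriction, and the active cutaneous vasodilation that makes warm
immersion an effective rewarming route (heat-stressed skin blood flow is
many times basal).  Muscle perfusion follows the cold-side factor with a
much higher floor, f_min_muscle = 0.7, and never exceeds basal:
vasoconstriction is predominantly cutaneous, and resting muscle blood flow
falls only moderately in cold.  Organ and head perfusion stay basal.

**Shivering.**  Whole-body power
Q = clamp(g_c (Tc_set − Tc) + g_s (Ts_set − Ts), 0, Q_max), with
g_c = 70 W/°C, g_s = 10 W/°C, Q_max = 350 W before scaling, all multiplied
by the single calibrated factor `shiver_scale` (see Calibration).
Shivering ceases entirely once the core drops below 32 °C — the clinically
standard cessation threshold — which visibly steepens the terminal part of
every cold trace.  Half of the shivering power enters the blood-pool
balance directly (shivering muscle is hyperaemic; its heat is convected
centrally) and half is deposited in trunk/proximal muscle tissue, where
shivering is concentrated.

## Numerics

Vertex-centred finite volumes per segment: nodes from the axis (r = 0) to
the surface (r = R), faces midway, layer interfaces on nodes.  Cells
straddling an interface carry exact per-tissue volume splits for heat
capacity, perfusion and metabolism (second-order accuracy of the
volumetric terms; this matters because the survival time amplifies
energy-balance errors roughly sixfold).  Interior layers grade their node
spacing toward the outer edge, where perfusion boundary layers live
(notably the strongly perfused head, δ ≈ 4 mm).

Time stepping is Crank–Nicolson (θ = ½; θ configurable up to backward
Euler, which is used for the stiff h → ∞ verification limit) with the
perfusion sink implicit; one tridiagonal solve per segment per step
(`scipy.linalg.solve_banded`).  Operator splitting: tissue step with the
blood temperature frozen, then a blood update computed from the
θ-averaged tissue temperatures so that pool and tissue perfusion
enthalpies cancel *exactly*.  A discrete energy ledger (boundary, sources,
perfusion, enthalpies) closes to round-off (≈ 1e-14 relative) and is
asserted to < 0.1 % in tests.

Defaults: dt = 1 s, nr = 160 nodes/segment, ≥ 4 nodes in the skin shell.
At the calibrated operating point, halving dt changes the anchor survival
time by < 0.02 % and doubling nr by 0.65 %.  A full 240-min scenario runs
in ~5–10 s on one CPU; the complete 15-scenario grid in under two minutes.
Divergence is guarded by a [−10, 60] °C sanity band.

Survival time is the first crossing of rectal 30.0 °C, linearly
interpolated between samples; the average cooling rate uses the
(37.2 − 30.0)/t_s convention so that rate × survival time ≡ 7.2 °C.
Rewarming runs start from the terminal state of the 0 °C still-fresh
cooling run with the whole field shifted so the rectal node reads exactly
30.0 °C, and report (37 − 30)/time-to-37 in °C/h.  If a run (forced air)
ends short of 37 °C, the partial rate (rectal gain)/(elapsed) is reported
so rate orderings remain well defined.

## Calibration protocol

Model structure (geometry, tissue table, control-law forms, f_min_muscle,
the 50/50 shivering split) is fixed first.  A single multiplier,
`shiver_scale`, scaling the shivering gains and cap together, is then
calibrated once by bisection against one anchor: still fresh water at
5 °C, h = 220 W/(m²·°C) → 136 min survival.  The frozen value is 2.3271
(`scripts/calibrate.py` reproduces it).  Every other number the package
produces — the other thirteen grid entries, the flow/salinity comparisons,
all rewarming rates — is a prediction of the calibrated model, not a fit.

The calibrated ceiling corresponds to ≈ 815 W of total shivering
thermogenesis (≈ 370 W convected to the core), above the ~350–500 W of
sustained human shivering.  This is a deliberate effective parameter: the
four-tissue body has no subcutaneous fat layer, so its shell conductance
is biased high, and the calibration absorbs that bias into the heat-
production term.  Treat the shivering wattage as an internal model
quantity, not a physiological prediction.

## What the scenario suite emulates — and what it does not

The built-in grid covers still/flowing fresh water (h = 220/460) at
5/2/0 °C, still/flowing seawater (h = 480/680) at 5/2/0/−2 °C, an
18.5 °C (h = 139) stabilization case, and 41/43 °C rewarming baths
(water h = 220/480, forced air h = 25, the top of the quoted 5–25 range).
Water composition enters *only* through h and the freezing floor (fresh
≥ 0 °C, salt ≥ −2 °C); flow *only* through the larger h.  No hydrodynamics,
no clothing, no inter-individual variation, no tissue freezing (the
−0.6 °C frostbite onset is reported as a threshold event only), no
after-drop rescue dynamics, no sweating.

Because every medium effect is funneled through a single saturating series
resistance (1/h + skin + shell), the model's sensitivity to h necessarily
flattens as h grows.  Published whole-body results that show near-linear
survival-vs-h behaviour up to h ≈ 680 W/(m²·°C) cannot be matched
simultaneously with the temperature sensitivity by any model of this
class; the shipped configuration balances the two.  Concretely, the
calibrated model reproduces the reference survival grid with exact
orderings everywhere and 9 of 13 non-anchor entries within ±10 %
(the still-fresh 2/0 °C and flowing-salt 2/−2 °C entries deviate by
11–16 %), a still-vs-flowing fresh-water reduction of ~14 % (reference
16 %), and a salt reduction of only ~3 % where ~13–14 % is quoted — the
latter is unreachable on physical grounds, since raising h from 480 to
680 changes the total core-to-water resistance by under 3 %.  Similarly,
skin cannot fall below −0.6 °C within 5 min of −2 °C immersion under the
bundled skin properties (contact-flux analysis puts the 5-min surface
near +0.5 °C); the model reaches that band later in the run.  Passing
tests therefore demonstrate internal consistency, verified numerics and
regime-level agreement — not that a real casualty's survival time is
predicted to ±10 %.

## Verification oracles

* Steady perfused cylinder: T(r) = T∞ + A I₀(m r) with m = √(ρ_b c_b ω_b/k),
  T∞ = T_b + q_m/(ρ_b c_b ω_b), A set by the Robin condition — evaluated via
  `scipy.special` independently of the solver; FD steady fields agree to
  < 0.05 °C.
* Lumped-capacitance decay, two-compartment blood–tissue relaxation,
  source-only heating, h → 0 and h → ∞ limits: closed forms asserted in
  the unit suite.
* A seeded scenario generator (`generate_scenario_suite`) drives
  randomized monotonicity properties (colder or better-coupled
  environments never lengthen the time to any core threshold).

## Known limitations

Single average body; 1-D radial conduction only (no axial or
inter-segment conduction); uniform h over the whole surface including the
head; Pennes perfusion with a single arterial temperature (no
countercurrent exchange, hence the effective-parameter calibration);
controls are quasi-static linear gains; the basal offset is tied to the
37/34.5 °C reference state.
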
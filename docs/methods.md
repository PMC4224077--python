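# Methods

## Model overview

`coagswitch` couples three components:

1. a **closed, well-mixed mass-action model of the coagulation cascade**
   in plasma (no flow terms), integrated as a stiff ODE system, whose
   readout is clot time — the first time fibrin crosses a fixed
   detection threshold;
2. a **turnover model for the six vitamin K-dependent proteins**
   (Factors II, VII, IX, X, proteins C and S) whose synthesis rates are
   scaled by an effective warfarin pre-factor; and
3. a **nomogram engine** that, for each time after warfarin
   discontinuation, finds the rivaroxaban exposures whose clot times
   match warfarin-monotherapy references under standardized trigger
   scenarios.

Units are molar and seconds everywhere inside the model; hours and µg/L
appear only at the reporting boundary.

## Cascade network

The extrinsic/common core follows the stoichiometric Hockin–Mann family:
TF binding of VII/VIIa, extrinsic tenase activation of Factors X and IX,
prothrombinase assembly (Xa:Va) with an explicit Xa:Va:II Michaelis
complex and meizothrombin intermediate, thrombin feedback activation of
V, VIII and XI, the intrinsic tenase (VIIIa:IXa) with A2-subunit
dissociation, stoichiometric inhibition by antithrombin, and TFPI
regulation of Xa and the TF:VIIa:Xa complex. Fibrinogen (9 µM) is
converted by thrombin with Michaelis–Menten kinetics (kcat 84 s⁻¹, Km
7.2 µM). A protein C/S branch (thrombin-activated protein C, APC:protein
S assembly on phospholipid binding sites held constant at 3.6 µM,
inactivation of Va and VIIIa) closes the anticoagulant side.

Three structural choices depart from the plain Hockin–Mann inventory and
are load-bearing:

* **Prothrombin activation by free Xa goes through an explicit Xa:II
  complex** (kon 10⁷ M⁻¹s⁻¹, Km 0.3 µM, kcat/Km equal to the classical
  lumped constant 7.5·10³ M⁻¹s⁻¹). Because rivaroxaban binds the free
  enzyme only, prothrombin occupancy of the Xa active site *shields* Xa
  from the drug. This is the textbook structure of competitive
  inhibition with respect to substrate, and it is what makes the
  warfarin–rivaroxaban interaction super-additive: at normal prothrombin
  (1.4 µM ≫ Km) the drug's grip is weak; under warfarin, prothrombin
  falls toward Km and the same exposure bites several-fold harder.
* **TFPI association constants are set an order of magnitude above
  free-plasma values** (Xa + TFPI 10⁷, TF:VIIa:Xa + TFPI 3.5·10⁹,
  TF:VIIa + Xa:TFPI 5.5·10⁸ M⁻¹s⁻¹), representing the surface-localized
  TFPI pool as a single effective constant. The stronger
  trigger-quenching steepens the clot-time response to vitamin K factor
  suppression; it is what places the titrated warfarin level for INR 2.5
  at 0.4.
* **The thrombin→XIa→IXa loop is stronger than in plasma-derived
  estimates** (IIa activates XI at 10⁵, XIa activates IX at
  10⁷ M⁻¹s⁻¹). At the PT timescale (12–30 s) this loop is inert; at the
  weak trigger (TF 10⁻¹⁴ M, roughly six molecules per mL) it is the only
  mechanism by which clotting can complete, including at the
  warfarin-suppressed reference states the corridor needs.

Boundary (buffered) species: the phospholipid binding sites and the
rivaroxaban pool — the drug is held at constant concentration during an
assay because the assay timescale (seconds–hours) is short against the
PK timescale, and binding consumes a negligible fraction of a
therapeutic exposure.

## Warfarin turnover model

Effective R- and S-warfarin levels (arbitrary units, 1.0 = the level
immediately after a dose of a racemic 1:1 therapy at steady state) scale
all six synthesis rates through

    W = 1 / ((R + 3.25·S)² + 1),

where 3.25 is the mean potency advantage of S-warfarin and the square
reflects the two vitamin K cycle steps inhibited. Each protein obeys

    d[Pᵢ]/dt = (ln2 / t½ᵢ) (kᵢ·W − [Pᵢ]),

with baselines kᵢ (fII 1.40 µM, fVII 10 nM, fIX 90 nM, fX 160 nM,
protein C 60 nM, protein S 140 nM) and half-lives (57, 5, 25.5, 37.5, 9,
60 h). Untreated steady state is exactly kᵢ; steady-state therapy sits
at kᵢ·W. Discontinuation decays R and S exponentially (half-lives 45 h
and 29 h for the median Caucasian patient; fast 20/18 h, slow 70/52 h;
Japanese S-half-lives are the Caucasian values times the relative
clearance 469.4/654.3 ≈ 0.7174, applied to all three speed variants).
The linear system with its time-varying source is integrated with LSODA
at rtol 10⁻¹⁰; tests verify it against the variation-of-constants
quadrature solution.

Titration to a target INR solves for the racemic level w (R = S = w) by
bracketed root finding on [0, 5] with an INR tolerance of 0.01,
exploiting monotonicity of INR in w. If the PT assay fails to clot
within its horizon during bracketing (extreme w), the horizon time is
used as a finite monotone surrogate clot time.

## Assays, INR and calibration

Trigger scenarios differ only in tissue-factor concentration: PT test
4·10⁻⁹ M, extrinsic strong 10⁻¹¹ M (the bleeding-risk/safety scenario),
extrinsic weak 10⁻¹⁴ M (the thrombosis-risk/efficacy scenario). INR =
(PT/PT₀)^ISI with ISI 1.0; PT₀ is the drug-free PT of the same
population profile (the Japanese baseline is longer because of the
reduced 0.5% Factor VII pre-activation), so INR is population-consistent
by construction.

Clot detection: fibrin reaching a fixed absolute threshold, expressed as
a calibrated fraction (7.80·10⁻⁴) of *normal* plasma fibrinogen. An
absolute rather than patient-relative threshold is deliberate: it makes
hypofibrinogenemic patients clot slower, as they do.

Five scalars are calibrated once (by `scripts/calibrate.py`; frozen in
`coagswitch/calibration.py`), in a strict sequence so each anchor pins
one scalar:

1. **clot threshold fraction** — clot-time *ratios* are invariant under
   a global rescaling of all rate constants, so the threshold is fixed
   first such that factor levels at W(0.4, 0.4) ≈ 0.257 prolong PT by
   exactly 2.5× (INR 2.5 at warfarin level 0.4);
2. **rate scale** (3.46) — a global multiplier on every rate constant;
   it compresses time exactly and maps the drug-free PT onto 12.0 s;
3. **rivaroxaban Ki** (128 nM) — the *effective* inhibition constant of
   the in-silico PT reagent, set so 200 µg/L prolongs PT from 12 to
   15 s. It sits far above the ~0.4 nM biochemical constant because
   plasma protein binding (~95%), reagent dilution and the documented
   insensitivity of PT reagents to Factor Xa inhibitors are all folded
   into one number;
4. **scenario drug sensitivities** (strong 102, weak 544) — the
   rivaroxaban analogue of the ISI: each trigger scenario's effective
   drug exposure is the plasma concentration times a reagent-sensitivity
   factor (1.0 for the PT test). The two factors are fixed so the
   drug-free (monotherapy) corridor bounds reproduce the established
   rivaroxaban therapeutic window: high-risk safety bound 300 µg/L and
   high-risk efficacy bound 100 µg/L, bracketing the steady-state
   exposure of the approved 20 mg once-daily dose. Without this degree
   of freedom a single effective potency cannot reconcile the PT
   reagent's 3-s response at 200 µg/L with corridor bounds at clinical
   exposures.

## Corridors and compliance

For a switch scenario (start INR, profile), warfarin is titrated to the
start INR; factors start at kᵢ·W and recover per the turnover model. At
each grid time the four bounds solve clot_time(state, c) = reference by
Brent root finding on c ∈ [0, 2000] µg/L (near machine precision on the
concentration axis; the clot-time residual is then limited only by the
ODE tolerance, ~10⁻⁵ relative). References are warfarin monotherapy clot
times at INR 4.0/5.0 (strong trigger → safety bounds) and 1.5/2.0 (weak
trigger → efficacy bounds), computed once per profile. A bound whose
reference is already exceeded by residual warfarin alone is clamped to
zero (the drug is not needed for efficacy, or not tolerable for safety,
at that time).

The PK overlay is a one-compartment, first-order absorption,
dose-proportional model (defaults CL/F 6.5 L/h, V/F 55 L, ka 1.4 h⁻¹ —
literature-class values for the atrial-fibrillation population; all
overridable in the configuration). Schedule compliance checks, per
dosing day, the day-end trough against the safety bound and the daily
mean against the efficacy bound, both at day end where the bounds are
tightest. No clot-time result depends on the PK parameters.

## Numerical choices

* Stiff integration: LSODA with analytic Jacobian assembled from the
  stoichiometry matrix; rtol 10⁻⁸, atol 10⁻¹⁴ M (concentrations span
  10⁻¹⁴–10⁻⁵ M). Refining tolerances 10× moves clot times by ≲10⁻⁵
  relative.
* Clot-time localization: the solver's event root finding on the
  threshold crossing (terminal, rising direction).
* Integration horizons: 600 s (PT), 4 h (strong), 16 h (weak); a
  non-clotting run returns `converged=False` with the horizon, never an
  exception.
* Degenerate inputs rejected with explicit errors: negative
  concentrations or times, non-positive half-lives, unknown profiles or
  scenario names, non-bracketing titration targets, unreachable
  threshold references (reported with the c_max searched).
* Full determinism: identical inputs produce bit-identical trajectories;
  there is no randomness anywhere in the pipeline (the CLI/config seed
  field is reserved).

## Problem sizes used in the tests

The default test suite runs corridors on a coarse 12-point grid over
0–168 h plus one hourly 169-point corridor (the base-case experiment,
~40 s on one CPU); panel robustness is probed at a single representative
time (48 h) for the extreme multipliers rather than all 24 profiles ×
full grids. These sizes are the package's own test design; the library
computes arbitrary grids.

## What the in-silico setup does and does not show

The synthetic patients here are deterministic "typical" individuals:
fixed baseline factor concentrations, fixed half-lives (three discrete
elimination speeds), no inter-individual variability, no measurement
noise, no vitamin K intake, no warfarin dosing dynamics (therapy is a
step change of effective levels), no PK interaction between drugs, and
no aPTT/contact pathway. Passing tests therefore demonstrate internal
consistency of the mechanism and calibration — not predictive coverage
of a patient population. INR observations from real discontinuation
studies can be overlaid (`coagswitch decay --overlay data.csv`) for
qualitative comparison only; nothing is fitted to them.

## Known limitations

* **Factor VIII/XI dependence of the weak trigger.** Because clotting at
  TF 10⁻¹⁴ M is necessarily carried by the intrinsic amplification loop,
  extreme VIII/XI under-expression (×0.01) abolishes weak-trigger
  clotting (a hemophilia-like phenotype) and ×5 over-expression shifts
  efficacy bounds tens of percent. The safety corridor is much less
  sensitive. Severe factor V deficiency, by contrast, is nearly inert
  here because prothrombin conversion at reagent-strength triggers is
  dominated by the Xa:II route.
* **Japanese baseline PT offset.** The 0.5% vs 1.0% Factor VII
  pre-activation difference produces a ~33% longer drug-free Japanese
  PT in this trigger-limited cascade — the right direction but likely an
  overestimate. Population comparisons are therefore made on
  INR-normalized quantities, where the S-warfarin clearance difference
  peaks about two days after discontinuation.
* **Effective constants.** The rivaroxaban Ki, the TFPI association
  rates and the scenario drug sensitivities are effective, calibrated
  quantities, not transferable biochemical measurements.
* The therapeutic-window anchors (300 and 100 µg/L) that fix the
  scenario sensitivities are design choices representing the previously
  established rivaroxaban window; shifting them rescales the corridor
  concentration axis without changing its shape or time course.
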
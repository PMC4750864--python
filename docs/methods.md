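# Methods

This note documents the model behind `apap_pbpk`: its equations and
assumptions, the parameters that matter, the numerical choices, the design
decisions taken where the problem was genuinely open, and what the test
suite does and does not establish.

## Model structure

**Transport.** The body is 14 well-stirred, perfusion-limited compartments.
Each perfused tissue obeys

    V^α dC^α/dt = Q^α (C_in − C^α/(Kp^α · BP)),

i.e. the venous outflow of a tissue is in equilibrium with the tissue at the
ratio Kp·BP (BP = 1 for acetaminophen, so blood and plasma concentrations
coincide). Topology: arterial blood feeds every organ except the lung; gut
and spleen outflows join the portal vein and pass through the liver, whose
arterial tributary is Q_liver − Q_gut − Q_spleen = 390 mL/min; all other
organs (and the liver's total outflow) return to the venous pool; the lung
carries the full cardiac output (6500 mL/min) from the venous to the
arterial pool. This is the unique arrangement under which the tabulated
flows conserve exactly — the validator checks ΣQ_systemic = Q_lung to
1e-9 relative and a positive hepatic artery flow.

**Elimination.** The kidney extracts a fixed fraction E = 0.02 of the drug
entering at the arterial concentration (rate E·Q_kidney·C_art). The liver
clears the drug through three Michaelis–Menten pathways — glucuronidation,
sulfation, oxidation — each with literature V_max (mmol/hr/kg body weight,
converted once to mmol/min for 70 kg) and K_m (mmol/L). The driving
concentration is the liver *outflow* concentration C_liver/(Kp·BP), the
convention under which plasma-referenced K_m values apply; `driving="tissue"`
switches to the raw tissue concentration for sensitivity work. At low
concentration the resulting total clearance is Q·CL_int/(Q+CL_int) ≈
0.35 L/min, in line with clinical acetaminophen clearance.

**Toxicity sub-model.** Oxidation produces NAPQI, which never leaves the
liver. It is removed only by bimolecular conjugation with glutathione:

    d[NAPQI]/dt = v_ox/V_liver − k_II [NAPQI][GSH]
    d[GSH]/dt   = k_gen_mult(t) · k_gen · (f_target·[GSH]_N − [GSH]) − k_II [NAPQI][GSH]

Regeneration is proportional to the deficit, so the pool approaches its
target from below and can never exceed it — the ceiling is structural, never
a clamp (a post-hoc assertion verifies [GSH] ≤ [GSH]_N·(1+1e-9)). Hepatic
zonation of GSH is deliberately not modelled; the liver is one well-mixed
pool. A dip below 30 % of the *normal* [GSH]_N is the injury criterion for
every scenario (the literature range is 20–30 %; 30 % is used throughout).

**Dosing.** Doses are instantaneous state discontinuities — the numerically
sound reading of Dirac inputs: the integrator stops at each dose time and
restarts with amount/V added to the target compartment (venous blood for IV;
gut tissue, scaled by F = 0.79, for oral). The gut-bolus convention for oral
dosing makes early absorption fast and the simulated Cmax high relative to
clinical tablets; an optional first-order absorption constant (`ka_per_min`,
default off) routes oral doses through a gut-lumen depot when absorption
kinetics matter.

## Parameters

Physiology (volumes, flows, partition coefficients) and kinetics are
tabulated defaults in `parameters.py`; every value is overridable through
the YAML config or directly in code. The constants that drive the science:

| parameter | default | units | role |
|---|---|---|---|
| V_max,g / K_m,g | 0.97 / 6.89 | mmol/hr/kg, mmol/L | glucuronidation |
| V_max,s / K_m,s | 0.011 / 0.097 | " | sulfation (saturates at therapeutic levels) |
| V_max,ox / K_m,ox | 0.035 / 0.28 | " | NAPQI production |
| E | 0.02 | — | renal extraction |
| F | 0.79 | — | oral bioavailability |
| k_II | 1.92e6 | mL/(mmol·min) | NAPQI–GSH conjugation |
| k_gen | 0.0026 | 1/min | GSH regeneration |
| [GSH]_N | 5.0701 | mmol/L | calibrated, see below |
| toxicity threshold | 0.30 | fraction of [GSH]_N | injury criterion |

**Calibration of [GSH]_N.** The normal hepatic GSH concentration is not a
tabulated input; it is fixed by the requirement that a single 15 g oral dose
(the accepted single-dose toxicity limit) depletes the pool by exactly 70 %.
`metrics.calibrate_baseline` bisects [GSH]_N on [1, 20] mmol/L to 1e-3
(depletion is monotone in [GSH]_N — a larger pool buffers the same NAPQI
burst — so the root is unique). The result, 5.070 mmol/L, is frozen as the
packaged default and sits inside the physiological range of hepatic GSH
(~4–8 mM); a test recomputes it from scratch and checks consistency.

**Scenarios.** All scenario schedules are continuous piecewise-linear
multipliers with constant extrapolation, built from constants in
`ScenarioConstants`:

* *Chronic use* — glucuronidation capacity ramps 1 → 1.5 (1 g per dose) or
  1 → 2.25 (≥2 g), sulfation 1 → 0.5 / 0.3, linearly over 4320 min (the
  first time at which altered clearance has been observed experimentally),
  then holds. Doses above 2 g reuse the 2 g tier, since induction beyond
  that dose is uncharacterized.
* *Alcohol* — t = 0 is the moment drinking stops. Oxidation capacity starts
  at 2.14 (the measured CYP2E1 increase after sustained heavy drinking) and
  decays linearly to 1 over 7200 min, consistent with the ~60 h CYP2E1
  half-life; the GSH pool starts at 0.5·[GSH]_N and its regeneration
  coefficient recovers linearly from 0.5 to 1 over 1440 min. The
  regeneration *target* stays [GSH]_N: the pool returns to normal.
* *Fasting/malnutrition* — constant factors: glucuronidation ×0.6, sulfation
  ×0.7, oxidation ×1.5, pool and regeneration rate ×0.75. Because
  malnutrition persists through the simulation, the reduced pool is treated
  as the steady state itself: regeneration targets 0.75·[GSH]_N
  (`gsh_target_fraction`). Without this, a drug-free fasting liver would
  drift back to normal within a day, which contradicts the premise of a
  chronically malnourished subject; with it, the zero-dose fasting run is
  exactly stationary. The fasting reduction of k_gen is not quantified in
  the source literature; the default mirrors the pool reduction (0.75) and
  is a documented config knob.
* *Chronic + alcohol* — pointwise product of the two schedules on a shared
  clock (exact, since each coefficient varies in at most one sub-scenario);
  the initial pool takes the alcohol halving.

Ramp forms are an interpretation: the source material specifies the
endpoints and windows but not the functional form, and linear interpolation
between the neutral value and the stated extreme is the simplest reading
consistent with the surrounding evidence (build-up to the first observation
time for chronic induction; decay from the maximum for the post-binge CYP
level).

## Headline metrics

* `assess_toxicity` — minimum GSH fraction (always relative to the normal
  [GSH]_N), its time, and the first threshold crossing, located by linear
  interpolation between grid points.
* `steady_state_reduction` — 100·(1 − mean GSH over the final 24 h /
  [GSH]_N). The windowed mean is robust to where dosing troughs fall on the
  grid; a >1 % drift between the last two windows triggers a warning.
* `gsh_auc_change_pct` — relative change in the area under the GSH curve
  between two runs. This is the metric behind the hormesis and alcohol
  comparisons: the GSH-sparing effect of chronic enzyme adaptation and the
  GSH cost of post-binge CYP induction are both expressed as percent changes
  of total GSH exposure over the 5-day run. (Cumulative NAPQI–GSH
  conjugation, `gsh_demand_auc`, is also provided; it tracks cumulative
  oxidation to within 1 % whenever GSH stays above half-normal, but it is
  not the quantity the published comparisons correspond to.)
* `find_minimal_cyp_multiplier` — bisection (±0.5 over [1, 100]) for the
  smallest constant oxidation-capacity factor that makes a regimen toxic;
  returns the toxic upper bound, so the returned value is toxic and one unit
  below it is not.
* `find_minimal_kgen_reduction` — smallest integer divisor of k_gen that
  makes a regimen toxic, with the crossing time; linear scan, since the
  answer is small and toxicity is monotone in the divisor.

## Numerics

States: 14 concentrations (mmol/L), liver GSH and NAPQI, five cumulative
route fluxes (mmol), one optional depot — 22 ODEs. The NAPQI conjugation
time-scale (k_II·[GSH] ≈ 1e4/min) makes the system stiff; LSODA integrates
it at rtol 1e-8 / atol 1e-10 with restarts at every dose time and scenario
breakpoint. Output lands on a 1-min grid that always contains the dose
times (post-dose values). A quasi-steady-state NAPQI mode
([NAPQI]* = v_ox/(V_L·k_II·[GSH])) removes the stiff scale; it agrees with
the full dynamics to 0.1 % on cumulative conjugation and is what the
fixed-step cross-check integrates. Degenerate inputs: zero doses are legal
and inert; negative concentrations beyond 1e4·atol, solver failures (with
the failing interval named) and GSH above its ceiling all raise
`IntegrationError`; a dose at or after `t_end` is rejected up front.

Verification stack (all in the suite):

* mass balance — absorbed input equals body burden plus the four route
  cumulants at every output time, to 1e-6 relative (observed: ~1e-15);
* flow conservation of the default physiology is exact;
* a collapsed one-blood-pool model with first-order renal clearance matches
  the closed-form exponential to 1e-6;
* an independently assembled fixed-step RK4 integration (transport matrix
  rebuilt by hand from the physiology table, dt = 1e-3 min, 6 h, QSS form)
  agrees with the adaptive solve to 0.1 % on every state;
* plasma AUC is dose-proportional to 0.5 % at trace doses (1 vs 2 mg);
* minimum GSH is strictly monotone in the oxidation multiplier.

## Problem sizes and reproducibility

The packaged experiments use the regimens the study design calls for:
chronic runs are 20 doses at 6 h intervals followed for 7200 min on a 1-min
grid; the overdose anchor runs 2880 min; calibration bisects ~15 such runs.
The full acceptance recomputation takes ~20 s on one CPU and the test suite
about a minute. The model is deterministic end to end: identical configs
produce byte-identical CSV output, which a test asserts.

## Known limitations

* Partition coefficients are tabulated inputs; they are not derived from
  tissue composition.
* Ethanol's own pharmacokinetics are not modelled — only its after-effects
  on CYP activity and the GSH pool.
* Oral absorption is a bolus by default; no dissolution, food effects or
  lag.
* NAPQI protein binding and downstream necrosis are outside the model; the
  30 % threshold is the injury criterion.
* Fasting does not shrink the liver (volume held constant).
* Scenario combinations other than chronic+alcohol (e.g. fasting+chronic)
  are intentionally not offered: the constituent effects act on the same
  reactions in conflicting directions and their composition is not
  established.
* Passing tests demonstrate internal consistency and agreement with the
  published predictions of this parameterization — not clinical validity
  for any individual patient; the scenarios are population-average
  caricatures of lifestyle states.

One published prediction does not reproduce from the printed parameters:
with the GSH regeneration coefficient divided by 5, therapeutic 6-hourly
dosing crosses the injury threshold after ~2.3 days in this implementation
(a closed-form estimate of net depletion gives the same ~2-day scale),
versus a reported "about 1 day". The discrepancy is reported as computed.
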
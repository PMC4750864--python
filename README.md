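# apap-pbpk

A whole-body physiologically-based pharmacokinetic (PBPK) model of
acetaminophen (APAP, paracetamol) disposition in an average 70 kg adult, with
a hepatic NAPQI/glutathione toxicity sub-model and time-dependent lifestyle
scenarios. It is aimed at pharmacokineticists and toxicologists who want to
ask quantitative "what if" questions about APAP-induced liver injury: how
deep does the hepatic glutathione (GSH) pool dip after a given regimen, and
how do chronic use, a binge-drinking episode, or malnutrition change the
answer?

## The model

The body is 14 well-stirred compartments (12 perfused organs plus arterial
and venous blood pools) connected by blood flow. For a non-eliminating
tissue α,

    V^α dC^α/dt = Q^α (C_art − C^α / (Kp^α · BP)),

with volume V, blood flow Q, tissue:plasma partition coefficient Kp and
blood:plasma ratio BP = 1. Gut and spleen drain through the portal vein into
the liver (hepatic artery flow = Q_liver − Q_gut − Q_spleen = 390 mL/min);
the lung sits in series between the blood pools carrying the cardiac output
(6500 mL/min). Doses are Dirac boluses: IV into venous blood, oral into gut
tissue scaled by the bioavailability F = 0.79.

Two organs eliminate drug:

* **Kidney** — non-enzymatic extraction of a fraction E = 0.02 of the drug
  entering at the arterial concentration: R = E · Q_kidney · C_art.
* **Liver** — three saturable pathways driven by the liver outflow
  concentration c, each R_j = Co_j(t) · V_max,j · c / (K_m,j + c):
  glucuronidation (0.97 mmol/hr/kg, K_m 6.89 mM), sulfation (0.011, 0.097)
  and CYP-mediated oxidation (0.035, 0.28), the last producing the reactive
  metabolite NAPQI.

NAPQI never leaves the liver; it is detoxified by bimolecular conjugation
with glutathione (k_II = 1.92·10⁶ mL/(mmol·min)). The GSH pool regenerates
in proportion to its deficit,

    d[GSH]/dt = k_gen ([GSH]_N − [GSH]) − k_II [NAPQI][GSH],  k_gen = 0.0026 min⁻¹,

so it can never exceed its normal level [GSH]_N. [GSH]_N is the one
non-tabulated constant: it is calibrated so that a single 15 g oral dose —
the accepted single-dose toxicity limit — depletes liver GSH by exactly
70 % (calibrated value: 5.070 mmol/L). A dip below 30 % of normal is the
liver-injury criterion.

The lifestyle scenarios are continuous piecewise-linear multipliers on the
pathway capacities and on GSH turnover:

| scenario | effect |
|---|---|
| chronic use | glucuronidation ramps up to 1.5× (1 g doses) or 2.25× (≥2 g), sulfation down to 0.5× / 0.3×, over 3 days |
| alcohol (binge ends at t=0) | oxidation starts at 2.14× and decays to 1× over 5 days; GSH pool halved, regeneration recovers over 24 h |
| fasting / malnutrition | glucuronidation ×0.6, sulfation ×0.7, oxidation ×1.5, GSH pool and regeneration ×0.75 (persistent state: regeneration targets the reduced level) |
| chronic + alcohol | pointwise product of the two schedules on a shared clock |

## Worked example

A single 15 g oral overdose, followed for 48 h:

```bash
apap-pbpk simulate --dose-g 15 --route oral --t-end 2880 \
    --out-csv ts.csv --out-json summary.json
```

prints (abridged):

```json
{
  "min_gsh_fraction": 0.2999581047500106,
  "time_of_min_gsh_min": 451.0,
  "toxic": true,
  "first_crossing_time_min": 446.4399331956108,
  "route_fractions": {
    "glucuronide": 0.5969600371017204,
    "sulfate": 0.09515409975435264,
    "oxidized": 0.20077468091489353,
    "renal": 0.10711098072275893
  },
  "mass_balance_error": 1.9940287583332726e-15
}
```

Liver GSH bottoms out at 30 % of normal 7.5 h after ingestion, crossing the
injury threshold at ~7.4 h — the calibration anchor reproduced end to end.
About 60 % of the absorbed dose leaves as the glucuronide, 10 % as the
sulfate, 20 % through oxidation (NAPQI) and 11 % unchanged in urine; the
solver conserves mass to machine precision. The CSV holds the full
trajectory (per-organ concentrations, GSH, NAPQI, cumulative route fluxes
and the applied scenario multipliers); `apap-pbpk metrics --csv ts.csv`
recomputes the toxicity metrics from it, and `apap-pbpk scenario-table`
prints every resolved default.

Library use mirrors the CLI:

```python
from apap_pbpk import simulate, assess_toxicity, steady_state_reduction
from apap_pbpk.dosing import Regimen
from apap_pbpk.scenarios import chronic_apap_schedule

res = simulate(Regimen.periodic(1.0, 360.0, 20, "oral"), 7200.0,
               scenario=chronic_apap_schedule(1.0))
print(steady_state_reduction(res))   # ~15.9 (% below normal GSH)
print(assess_toxicity(res).toxic)    # False
```

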
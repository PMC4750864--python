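"""Physiological and kinetic parameter sets for the acetaminophen PBPK model.

The model describes an average 70 kg adult as 14 well-stirred compartments
(12 perfused tissues plus arterial and venous blood pools) connected by blood
flow, with hepatic metabolism through three saturable pathways
(glucuronidation, sulfation, CYP-mediated oxidation to NAPQI), non-enzymatic
renal extraction, and a liver glutathione (GSH) pool that detoxifies NAPQI.

Internal unit system: mmol, mL, min. Concentrations are mmol/L; pathway Vmax
values are stored in the literature unit mmol/(hr.kg body weight) and converted
to mmol/min at model-build time (``vmax * body_weight / 60``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "TissueCompartment",
    "Physiology",
    "MetabolicPathway",
    "GshParams",
    "ScenarioConstants",
    "KineticParams",
    "default_physiology",
    "default_kinetics",
    "validate_physiology",
    "APAP_MOLAR_MASS_G_MOL",
    "GSH_NORMAL_MMOL_L",
]

#: Molar mass of acetaminophen (C8H9NO2), g/mol; used for g -> mmol conversion.
APAP_MOLAR_MASS_G_MOL = 151.16

#: Normal hepatic glutathione concentration, mmol/L. This is the one model
#: constant that is not a tabulated literature value: it is fixed by requiring
#: that a single 15 g oral dose depletes liver GSH by 70 % (the accepted
#: single-dose toxicity limit). ``metrics.calibrate_baseline`` recomputes it
#: from scratch and a regression test checks the frozen value stays consistent.
GSH_NORMAL_MMOL_L = 5.0701

# Compartment roles.
ROLE_NON_ELIMINATING = "non-eliminating"
ROLE_LIVER = "liver"
ROLE_KIDNEY = "kidney"
ROLE_LUNG = "lung"
ROLE_ARTERIAL = "arterial-blood"
ROLE_VENOUS = "venous-blood"

_UNIQUE_ROLES = (ROLE_LIVER, ROLE_KIDNEY, ROLE_LUNG, ROLE_ARTERIAL, ROLE_VENOUS)

#: Names of the organs whose venous outflow drains into the portal vein and
#: therefore enters the liver rather than the systemic venous pool.
PORTAL_ORGANS = ("gut", "spleen")


@dataclass(frozen=True)
class TissueCompartment:
    """One perfused organ.

    Parameters
    ----------
    name:
        Identifier, e.g. ``"liver"``.
    volume_ml:
        Anatomical volume V (mL).
    blood_flow_ml_min:
        Blood flow Q into the compartment (mL/min). For the two blood pools
        this is zero; their turnover is governed by the lung (cardiac
        output) flow.
    partition_coefficient:
        Tissue:plasma equilibrium ratio Kp (dimensionless). The compartment's
        venous outflow concentration is ``C_tissue / (Kp * BP)``.
    role:
        One of ``non-eliminating``, ``liver``, ``kidney``, ``lung``,
        ``arterial-blood``, ``venous-blood``.
    """

    name: str
    volume_ml: float
    blood_flow_ml_min: float
    partition_coefficient: float
    role: str = ROLE_NON_ELIMINATING


@dataclass(frozen=True)
class Physiology:
    """Whole-body compartment set plus the body-level constants."""

    compartments: tuple[TissueCompartment, ...]
    body_weight_kg: float = 70.0
    blood_plasma_ratio: float = 1.0

    def by_name(self, name: str) -> TissueCompartment:
        for c in self.compartments:
            if c.name == name:
                return c
        raise KeyError(f"no compartment named {name!r}")

    def by_role(self, role: str) -> TissueCompartment:
        matches = [c for c in self.compartments if c.role == role]
        if len(matches) != 1:
            raise ValueError(f"expected exactly one compartment with role {role!r}, "
                             f"found {len(matches)}")
        return matches[0]

    @property
    def cardiac_output_ml_min(self) -> float:
        """Total blood flow through the lung (mL/min)."""
        return self.by_role(ROLE_LUNG).blood_flow_ml_min

    @property
    def hepatic_artery_flow_ml_min(self) -> float:
        """Arterial tributary of the liver: Q_liver - Q_gut - Q_spleen.

        Gut and spleen drain into the portal vein, so the liver's total flow
        is the sum of the hepatic artery and the two portal tributaries. This
        is the only arrangement under which the tabulated flows conserve
        (systemic venous returns sum exactly to the lung flow).
        """
        q_liver = self.by_role(ROLE_LIVER).blood_flow_ml_min
        q_portal = sum(self.by_name(n).blood_flow_ml_min for n in PORTAL_ORGANS)
        return q_liver - q_portal

    def systemic_return_ml_min(self) -> float:
        """Sum of venous returns into the venous pool (mL/min).

        Counts every perfused tissue's outflow except the portal organs
        (whose outflow passes through the liver and is counted once via the
        liver's total flow) and the lung/blood pools.
        """
        skip = set(PORTAL_ORGANS)
        total = 0.0
        for c in self.compartments:
            if c.name in skip or c.role in (ROLE_LUNG, ROLE_ARTERIAL, ROLE_VENOUS):
                continue
            total += c.blood_flow_ml_min
        return total


# The 14-row default physiology of a 70 kg adult: per-organ volume (mL),
# blood flow (mL/min) and APAP tissue:plasma partition coefficient.
_DEFAULT_TABLE = (
    # name, volume_ml, flow_ml_min, Kp, role
    ("adipose", 8372.0, 325.0, 0.312, ROLE_NON_ELIMINATING),
    ("bone", 5992.0, 325.0, 0.682, ROLE_NON_ELIMINATING),
    ("brain", 1400.0, 780.0, 1.05, ROLE_NON_ELIMINATING),
    ("gut", 1197.0, 1105.0, 0.92, ROLE_NON_ELIMINATING),
    ("heart", 329.0, 260.0, 0.852, ROLE_NON_ELIMINATING),
    ("kidney", 308.0, 1235.0, 0.906, ROLE_KIDNEY),
    ("liver", 1799.0, 1625.0, 0.93, ROLE_LIVER),
    ("lung", 532.0, 6500.0, 0.87, ROLE_LUNG),
    ("muscle", 28000.0, 1105.0, 0.88, ROLE_NON_ELIMINATING),
    ("rest_of_body", 13895.0, 520.0, 1.0, ROLE_NON_ELIMINATING),
    ("skin", 2597.0, 325.0, 0.853, ROLE_NON_ELIMINATING),
    ("spleen", 182.0, 130.0, 0.915, ROLE_NON_ELIMINATING),
    ("arterial_blood", 1799.0, 0.0, 1.0, ROLE_ARTERIAL),
    ("venous_blood", 3598.0, 0.0, 1.0, ROLE_VENOUS),
)


def default_physiology() -> Physiology:
    """The default 14-compartment physiology of an average 70 kg adult."""
    comps = tuple(TissueCompartment(*row) for row in _DEFAULT_TABLE)
    return Physiology(compartments=comps)


@dataclass(frozen=True)
class MetabolicPathway:
    """One hepatic Michaelis-Menten clearance pathway.

    vmax is in mmol/(hr.kg body weight); km in mmol/L.
    """

    name: str
    vmax: float
    km: float

    def vmax_mmol_min(self, body_weight_kg: float) -> float:
        """Whole-liver maximum rate in mmol/min for the given body weight."""
        return self.vmax * body_weight_kg / 60.0


@dataclass(frozen=True)
class GshParams:
    """Hepatic glutathione turnover and NAPQI conjugation constants.

    d[GSH]/dt = k_gen * ([GSH]_N - [GSH]) - k_II * [NAPQI] * [GSH]

    Regeneration is proportional to the deficit, so the pool can never exceed
    its normal level; no clamping is applied anywhere.
    """

    k_gen: float = 0.0026  # 1/min
    k_ii: float = 1.92e6  # mL/(mmol.min); bimolecular NAPQI-GSH constant
    gsh_normal: float = GSH_NORMAL_MMOL_L  # mmol/L
    toxicity_fraction: float = 0.30  # injury threshold as fraction of normal

    @property
    def k_ii_l_per_mmol_min(self) -> float:
        """k_II converted to L/(mmol.min) for use with mmol/L concentrations."""
        return self.k_ii / 1000.0


@dataclass(frozen=True)
class ScenarioConstants:
    """Constants of the time-dependent lifestyle scenarios.

    Chronic use induces glucuronidation (Co_g) and depresses sulfation (Co_s),
    ramping linearly over ``chronic_ramp_min``; the maxima depend on the
    per-administration dose (the 2 g values are reused for any larger dose).
    A binge-drinking episode leaves CYP activity at ``alcohol_cyp_factor``,
    decaying linearly back to normal over ``alcohol_cyp_ramp_min``, and halves
    the hepatic GSH pool and its regeneration rate, the latter recovering over
    ``alcohol_gsh_ramp_min``. Fasting/malnutrition applies constant factors.
    """

    co_g_max_1g: float = 1.5
    co_s_max_1g: float = 0.5
    co_g_max_2g: float = 2.25
    co_s_max_2g: float = 0.3
    chronic_ramp_min: float = 4320.0  # 3 days

    alcohol_cyp_factor: float = 2.14
    alcohol_cyp_ramp_min: float = 7200.0  # 5 days
    alcohol_gsh_fraction: float = 0.5
    alcohol_gsh_ramp_min: float = 1440.0  # 1 day

    fasting_co_g: float = 0.6
    fasting_co_s: float = 0.7
    fasting_co_ox: float = 1.5
    fasting_gsh_fraction: float = 0.75
    # The fasting reduction of the regeneration rate is not quantified in the
    # source literature; by default it mirrors the pool reduction.
    fasting_k_gen_fraction: float = 0.75

    def chronic_maxima(self, dose_g: float) -> tuple[float, float]:
        """(Co_g_max, Co_s_max) for a given per-administration dose.

        Doses of 2 g and above use the 2 g tier; smaller doses the 1 g tier.
        """
        if dose_g >= 2.0:
            return self.co_g_max_2g, self.co_s_max_2g
        return self.co_g_max_1g, self.co_s_max_1g


@dataclass(frozen=True)
class KineticParams:
    """All drug-specific kinetic constants of the model."""

    pathways: tuple[MetabolicPathway, ...] = (
        MetabolicPathway("glucuronidation", vmax=0.97, km=6.89),
        MetabolicPathway("sulfation", vmax=0.011, km=0.097),
        MetabolicPathway("oxidation", vmax=0.035, km=0.28),
    )
    renal_extraction: float = 0.02  # E, dimensionless
    oral_bioavailability: float = 0.79  # F, dimensionless
    gsh: GshParams = field(default_factory=GshParams)
    scenario_constants: ScenarioConstants = field(default_factory=ScenarioConstants)
    apap_molar_mass: float = APAP_MOLAR_MASS_G_MOL  # g/mol

    def pathway(self, name: str) -> MetabolicPathway:
        for p in self.pathways:
            if p.name == name:
                return p
        raise KeyError(f"no pathway named {name!r}")

    def with_gsh_normal(self, gsh_normal: float) -> "KineticParams":
        return replace(self, gsh=replace(self.gsh, gsh_normal=gsh_normal))

    def with_k_gen_scaled(self, factor: float) -> "KineticParams":
        return replace(self, gsh=replace(self.gsh, k_gen=self.gsh.k_gen * factor))


def default_kinetics() -> KineticParams:
    """The default kinetic parameter set (literature values, see class docs)."""
    return KineticParams()


def validate_physiology(p: Physiology, rtol: float = 1e-9) -> list[str]:
    """Check all physiology invariants; return a list of violation messages.

    An empty list means the parameter set is internally consistent:
    positive volumes, non-negative flows, positive partition coefficients,
    exactly one compartment per special role, a positive hepatic arterial
    flow, and conservation of flow (systemic venous returns equal the lung
    flow, i.e. cardiac output, within relative tolerance ``rtol``).
    """
    violations: list[str] = []

    for c in p.compartments:
        if not c.volume_ml > 0:
            violations.append(f"{c.name}: volume must be > 0 (got {c.volume_ml})")
        if c.blood_flow_ml_min < 0:
            violations.append(f"{c.name}: blood flow must be >= 0 (got {c.blood_flow_ml_min})")
        if not c.partition_coefficient > 0:
            violations.append(
                f"{c.name}: partition coefficient must be > 0 (got {c.partition_coefficient})")

    for role in _UNIQUE_ROLES:
        n = sum(1 for c in p.compartments if c.role == role)
        if n != 1:
            violations.append(f"expected exactly one compartment with role {role!r}, found {n}")
    if violations:
        return violations  # topology checks below need the unique roles

    for name in PORTAL_ORGANS:
        try:
            p.by_name(name)
        except KeyError:
            violations.append(f"portal organ {name!r} missing")
    if violations:
        return violations

    if not p.body_weight_kg > 0:
        violations.append(f"body weight must be > 0 (got {p.body_weight_kg})")
    if not p.blood_plasma_ratio > 0:
        violations.append(f"blood:plasma ratio must be > 0 (got {p.blood_plasma_ratio})")

    q_ha = p.hepatic_artery_flow_ml_min
    if not q_ha > 0:
        violations.append(
            f"hepatic arterial flow Q_liver - Q_gut - Q_spleen must be > 0 (got {q_ha} mL/min)")

    co = p.cardiac_output_ml_min
    ret = p.systemic_return_ml_min()
    if not math.isclose(ret, co, rel_tol=rtol, abs_tol=0.0):
        violations.append(
            f"flow not conserved: systemic venous returns {ret} mL/min "
            f"!= lung flow {co} mL/min")

    return violations
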
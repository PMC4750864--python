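"""The coupled PBPK + glutathione ODE system and its integrator.

State layout (length 14 + 2 + 5 + 1 = 22):

* 14 APAP concentrations, one per compartment (mmol/L), in physiology order;
* liver GSH and liver NAPQI concentrations (mmol/L);
* five cumulative elimination fluxes (mmol): glucuronide, sulfate, oxidized,
  renal, NAPQI-GSH conjugate;
* an optional gut-lumen depot (mmol), used only when a first-order oral
  absorption constant is configured.

Transport follows the perfusion-limited convention: a compartment's venous
outflow concentration is C/(Kp*BP). Gut and spleen drain into the liver
(portal vein); every other organ returns to the venous pool; the lung sits in
series between the venous and arterial pools carrying the full cardiac
output. Hepatic metabolism (three Michaelis-Menten pathways) is driven by the
liver outflow concentration by default, the convention under which
plasma-referenced Km values apply; renal extraction removes a fixed fraction
E of the drug entering the kidney at the arterial concentration.

NAPQI is liver-local: it has no transport terms and is consumed only by
bimolecular conjugation with GSH. Because the conjugation constant is large
(~2e3 L/(mmol.min)) the system is stiff and is integrated with an implicit
solver; an optional quasi-steady-state (QSS) mode treats NAPQI algebraically.

Doses are state discontinuities: the integrator is restarted at every dose
time with amount/V added to the target compartment's concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .dosing import Regimen, dose_to_moles, expand_regimen
from .parameters import (
    KineticParams,
    Physiology,
    ROLE_ARTERIAL,
    ROLE_KIDNEY,
    ROLE_LIVER,
    ROLE_LUNG,
    ROLE_VENOUS,
    default_kinetics,
    default_physiology,
    validate_physiology,
)
from .scenarios import ScenarioModifiers, neutral_modifiers

__all__ = [
    "SolverSettings",
    "SimulationResult",
    "IntegrationError",
    "PbpkModel",
    "simulate",
    "simulate_one_compartment",
    "tissue_derivative",
    "liver_inflow_concentration",
    "michaelis_menten_rate",
    "renal_elimination_rate",
    "gsh_derivative",
    "napqi_derivative",
]

CUM_LABELS = ("glucuronide", "sulfate", "oxidized", "renal", "gsh_conjugated")


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails or produces an invalid state."""


@dataclass(frozen=True)
class SolverSettings:
    """Numerical settings for the stiff integrator."""

    rtol: float = 1e-8
    atol: float = 1e-10  # mmol/L
    max_step_min: float = math.inf
    grid_min: float = 1.0  # output grid spacing
    method: str = "LSODA"

    def __post_init__(self) -> None:
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("tolerances must be > 0")
        if self.grid_min <= 0:
            raise ValueError("output grid spacing must be > 0")


# ---------------------------------------------------------------------------
# Elementary rate laws, exposed for direct testing and reuse.
# ---------------------------------------------------------------------------

def tissue_derivative(c_tissue: float, c_in: float, volume_ml: float,
                      blood_flow_ml_min: float, partition_coefficient: float,
                      blood_plasma_ratio: float = 1.0) -> float:
    """Perfusion-limited balance for a non-eliminating tissue (mmol/L/min).

    dC/dt = (Q/V) * (c_in - C/(Kp*BP)).
    """
    c_out = c_tissue / (partition_coefficient * blood_plasma_ratio)
    return blood_flow_ml_min / volume_ml * (c_in - c_out)


def liver_inflow_concentration(c_arterial: float, c_gut_out: float, c_spleen_out: float,
                               physiology: Physiology) -> float:
    """Flow-weighted mix of hepatic-artery and portal inflows (mmol/L)."""
    q_liver = physiology.by_role(ROLE_LIVER).blood_flow_ml_min
    q_gut = physiology.by_name("gut").blood_flow_ml_min
    q_spleen = physiology.by_name("spleen").blood_flow_ml_min
    q_ha = physiology.hepatic_artery_flow_ml_min
    return (q_ha * c_arterial + q_gut * c_gut_out + q_spleen * c_spleen_out) / q_liver


def michaelis_menten_rate(c_driving: float, vmax: float, km: float,
                          multiplier: float, body_weight_kg: float) -> float:
    """Whole-organ saturable clearance rate (mmol/min).

    ``vmax`` is in mmol/(hr.kg body weight); the multiplier is the scenario
    coefficient applied to the pathway's capacity.
    """
    vmax_min = vmax * body_weight_kg / 60.0
    return multiplier * vmax_min * c_driving / (km + c_driving)


def renal_elimination_rate(c_arterial: float, physiology: Physiology,
                           kinetics: KineticParams) -> float:
    """Non-enzymatic extraction in the kidney (mmol/min): E * Q_kidney * C_art."""
    q_kidney_l = physiology.by_role(ROLE_KIDNEY).blood_flow_ml_min / 1000.0
    return kinetics.renal_extraction * q_kidney_l * c_arterial


def gsh_derivative(gsh: float, napqi: float, kinetics: KineticParams,
                   k_gen_multiplier: float = 1.0) -> float:
    """d[GSH]/dt (mmol/L/min): deficit-proportional regeneration minus conjugation."""
    g = kinetics.gsh
    regen = k_gen_multiplier * g.k_gen * (g.gsh_normal - gsh)
    return regen - g.k_ii_l_per_mmol_min * napqi * gsh


def napqi_derivative(napqi: float, gsh: float, oxidation_rate_mmol_min: float,
                     liver_volume_ml: float, kinetics: KineticParams) -> float:
    """d[NAPQI]/dt (mmol/L/min). NAPQI never leaves the liver."""
    v_l = liver_volume_ml / 1000.0
    return oxidation_rate_mmol_min / v_l - kinetics.gsh.k_ii_l_per_mmol_min * napqi * gsh


# ---------------------------------------------------------------------------
# Assembled model
# ---------------------------------------------------------------------------

class PbpkModel:
    """Precomputed arrays and the right-hand side of the full ODE system.

    Parameters
    ----------
    driving:
        ``"outflow"`` (default) drives hepatic metabolism with the liver's
        venous-equilibrated concentration C/(Kp*BP); ``"tissue"`` uses the raw
        tissue concentration.
    qss_napqi:
        Treat NAPQI as being in quasi-steady state (algebraic); removes the
        stiff conjugation time-scale. The reported NAPQI trace is then the
        QSS value and conjugation flux equals oxidation flux.
    ka_per_min:
        Optional first-order oral absorption constant; when set, oral doses
        enter a gut-lumen depot emptying into gut tissue at this rate.
    """

    def __init__(self, physiology: Physiology | None = None,
                 kinetics: KineticParams | None = None,
                 scenario: ScenarioModifiers | None = None,
                 driving: str = "outflow",
                 qss_napqi: bool = False,
                 ka_per_min: float | None = None) -> None:
        self.physiology = physiology or default_physiology()
        self.kinetics = kinetics or default_kinetics()
        self.scenario = scenario or neutral_modifiers()
        if driving not in ("outflow", "tissue"):
            raise ValueError("driving must be 'outflow' or 'tissue'")
        self.driving = driving
        self.qss_napqi = qss_napqi
        self.ka_per_min = ka_per_min

        problems = validate_physiology(self.physiology)
        if problems:
            raise ValueError("invalid physiology: " + "; ".join(problems))

        p = self.physiology
        comps = p.compartments
        self.names = [c.name for c in comps]
        self.n_comp = len(comps)
        bp = p.blood_plasma_ratio

        self.i_liver = self.names.index(p.by_role(ROLE_LIVER).name)
        self.i_kidney = self.names.index(p.by_role(ROLE_KIDNEY).name)
        self.i_lung = self.names.index(p.by_role(ROLE_LUNG).name)
        self.i_art = self.names.index(p.by_role(ROLE_ARTERIAL).name)
        self.i_ven = self.names.index(p.by_role(ROLE_VENOUS).name)
        self.i_gut = self.names.index("gut")
        self.i_spleen = self.names.index("spleen")

        self.volume_ml = np.array([c.volume_ml for c in comps])
        self.volume_l = self.volume_ml / 1000.0
        self.flow = np.array([c.blood_flow_ml_min for c in comps])
        self.kp_bp = np.array([c.partition_coefficient * bp for c in comps])
        self.kp_bp[self.i_art] = 1.0  # blood pools hold blood concentration
        self.kp_bp[self.i_ven] = 1.0
        self.qv = self.flow / self.volume_ml  # 1/min

        # Venous-return weights: every systemic organ except the portal
        # tributaries (their outflow is routed through the liver) and the
        # lung/blood pools.
        w = self.flow.copy()
        for i in (self.i_gut, self.i_spleen, self.i_lung, self.i_art, self.i_ven):
            w[i] = 0.0
        self.venous_weights = w
        self.q_ha = p.hepatic_artery_flow_ml_min
        self.q_liver = self.flow[self.i_liver]
        self.q_lung = self.flow[self.i_lung]

        k = self.kinetics
        bw = p.body_weight_kg
        self.vmax_min = np.array([pw.vmax_mmol_min(bw) for pw in k.pathways])
        self.km = np.array([pw.km for pw in k.pathways])
        # Pathway order fixed as (glucuronidation, sulfation, oxidation).
        expected = ("glucuronidation", "sulfation", "oxidation")
        got = tuple(pw.name for pw in k.pathways)
        if got != expected:
            raise ValueError(f"pathways must be {expected}, got {got}")
        self.k_ii_l = k.gsh.k_ii_l_per_mmol_min
        self.k_gen = k.gsh.k_gen
        self.gsh_normal = k.gsh.gsh_normal
        # Level the regeneration law pulls toward; below normal only for
        # persistent states (e.g. ongoing malnutrition).
        self.gsh_target = self.scenario.gsh_target_fraction * self.gsh_normal
        self.renal_cl_l_min = k.renal_extraction * self.flow[self.i_kidney] / 1000.0

        # State layout offsets.
        self.ix_gsh = self.n_comp
        self.ix_napqi = self.n_comp + 1
        self.ix_cum = self.n_comp + 2  # 5 slots
        self.ix_depot = self.n_comp + 7
        self.n_state = self.n_comp + 8

    # -- state helpers ------------------------------------------------------

    def initial_state(self) -> np.ndarray:
        y0 = np.zeros(self.n_state)
        y0[self.ix_gsh] = self.scenario.initial_gsh_fraction * self.gsh_normal
        return y0

    def apply_dose(self, y: np.ndarray, moles: float, target: str) -> None:
        """Add a bolus (mmol) to the target compartment, in place."""
        if target == "gut" and self.ka_per_min is not None:
            y[self.ix_depot] += moles
        else:
            i = self.names.index(target)
            y[i] += moles / self.volume_l[i]

    def metabolic_rates(self, c_liver: float, co_g: float, co_s: float,
                        co_ox: float) -> np.ndarray:
        """(glucuronidation, sulfation, oxidation) rates in mmol/min."""
        c_drv = max(c_liver / self.kp_bp[self.i_liver], 0.0) \
            if self.driving == "outflow" else max(c_liver, 0.0)
        mult = np.array([co_g, co_s, co_ox])
        return mult * self.vmax_min * c_drv / (self.km + c_drv)

    def napqi_qss(self, oxidation_rate: float, gsh: float) -> float:
        """Quasi-steady-state NAPQI concentration (mmol/L)."""
        denom = self.volume_l[self.i_liver] * self.k_ii_l * max(gsh, 1e-30)
        return oxidation_rate / denom

    # -- right-hand side ----------------------------------------------------

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        c = y[: self.n_comp]
        gsh = y[self.ix_gsh]
        napqi = y[self.ix_napqi]
        s = self.scenario
        co_g = float(np.interp(t, s.co_g.times, s.co_g.values))
        co_s = float(np.interp(t, s.co_s.times, s.co_s.values))
        co_ox = float(np.interp(t, s.co_ox.times, s.co_ox.values))
        kg_mult = float(np.interp(t, s.k_gen_mult.times, s.k_gen_mult.values))

        c_out = c / self.kp_bp
        c_art = c[self.i_art]
        c_ven = c[self.i_ven]

        d = np.zeros_like(y)
        # Generic perfused tissues fed by arterial blood.
        d[: self.n_comp] = self.qv * (c_art - c_out)

        # Lung: in series, fed by the venous pool.
        d[self.i_lung] = self.qv[self.i_lung] * (c_ven - c_out[self.i_lung])
        # Arterial pool: receives the lung outflow at cardiac output.
        d[self.i_art] = self.q_lung / self.volume_ml[self.i_art] * (c_out[self.i_lung] - c_art)
        # Venous pool: collects systemic returns.
        d[self.i_ven] = (self.venous_weights @ c_out - self.q_lung * c_ven) \
            / self.volume_ml[self.i_ven]

        # Liver: portal + arterial inflow, minus metabolism.
        c_in = (self.q_ha * c_art + self.flow[self.i_gut] * c_out[self.i_gut]
                + self.flow[self.i_spleen] * c_out[self.i_spleen]) / self.q_liver
        rates = self.metabolic_rates(c[self.i_liver], co_g, co_s, co_ox)
        v_liver_l = self.volume_l[self.i_liver]
        d[self.i_liver] = self.qv[self.i_liver] * (c_in - c_out[self.i_liver]) \
            - rates.sum() / v_liver_l

        # Kidney: extraction of a fraction E of the entering (arterial) drug.
        renal_rate = self.renal_cl_l_min * max(c_art, 0.0)
        d[self.i_kidney] -= renal_rate / self.volume_l[self.i_kidney]

        # Optional gut-lumen depot.
        if self.ka_per_min is not None:
            depot = y[self.ix_depot]
            d[self.ix_depot] = -self.ka_per_min * depot
            d[self.i_gut] += self.ka_per_min * depot / self.volume_l[self.i_gut]

        v_ox = rates[2]
        regen = kg_mult * self.k_gen * (self.gsh_target - gsh)
        if self.qss_napqi:
            conj_flux = v_ox  # mmol/min, production = consumption
            d[self.ix_gsh] = regen - v_ox / v_liver_l
            d[self.ix_napqi] = 0.0
        else:
            conj_conc_rate = self.k_ii_l * max(napqi, 0.0) * max(gsh, 0.0)
            conj_flux = conj_conc_rate * v_liver_l
            d[self.ix_gsh] = regen - conj_conc_rate
            d[self.ix_napqi] = v_ox / v_liver_l - conj_conc_rate

        d[self.ix_cum + 0] = rates[0]
        d[self.ix_cum + 1] = rates[1]
        d[self.ix_cum + 2] = v_ox
        d[self.ix_cum + 3] = renal_rate
        d[self.ix_cum + 4] = conj_flux
        return d


@dataclass
class SimulationResult:
    """Time grid, trajectories and bookkeeping of one simulation.

    ``conc`` has one column per compartment in physiology order (mmol/L);
    ``cum`` columns follow :data:`CUM_LABELS` (mmol). Dose times appear on
    the grid with their post-dose values. ``traces`` holds the applied
    scenario multipliers on the grid.
    """

    time: np.ndarray
    conc: np.ndarray
    gsh: np.ndarray
    napqi: np.ndarray
    cum: np.ndarray
    depot: np.ndarray
    traces: dict[str, np.ndarray]
    compartment_names: list[str]
    physiology: Physiology
    kinetics: KineticParams
    scenario: ScenarioModifiers
    dose_inputs: list[tuple[float, float]] = field(default_factory=list)  # (time, mmol)

    @property
    def absorbed_mmol(self) -> float:
        """Total systemically available drug input over the run."""
        return sum(m for _, m in self.dose_inputs)

    def administered_mmol(self) -> np.ndarray:
        """Cumulative systemically available input at each grid time."""
        adm = np.zeros_like(self.time)
        for t0, m in self.dose_inputs:
            adm += np.where(self.time >= t0, m, 0.0)
        return adm

    def cum_route(self, label: str) -> np.ndarray:
        return self.cum[:, CUM_LABELS.index(label)]

    def plasma(self) -> np.ndarray:
        """Venous blood concentration (mmol/L); equals plasma since BP = 1."""
        i = self.compartment_names.index(
            self.physiology.by_role(ROLE_VENOUS).name)
        return self.conc[:, i]

    def gsh_fraction(self) -> np.ndarray:
        """Liver GSH relative to the normal (unstressed) concentration."""
        return self.gsh / self.kinetics.gsh.gsh_normal

    def body_burden_mmol(self) -> np.ndarray:
        """APAP present in all compartments plus the depot (mmol)."""
        volumes = np.array([self.physiology.by_name(n).volume_ml / 1000.0
                            for n in self.compartment_names])
        return self.conc @ volumes + self.depot

    def mass_balance_error(self) -> float:
        """Max relative deviation of input vs. (present + eliminated)."""
        adm = self.administered_mmol()
        accounted = self.body_burden_mmol() + self.cum[:, :4].sum(axis=1)
        scale = max(adm.max(), 1e-300)
        return float(np.max(np.abs(adm - accounted)) / scale)


# ---------------------------------------------------------------------------
# Event-aware integration
# ---------------------------------------------------------------------------

def _integrate_segments(rhs, y0: np.ndarray, t_end: float,
                        jumps: list[tuple[float, np.ndarray]],
                        settings: SolverSettings,
                        breakpoints: tuple[float, ...] = ()) -> tuple[np.ndarray, np.ndarray]:
    """Integrate dy/dt = rhs with state jumps, restarting at each jump.

    ``jumps`` is a list of (time, delta_state). Returns the output grid and
    the state matrix (rows = times); jump times carry post-jump values.
    """
    jump_map: dict[float, np.ndarray] = {}
    for t0, dy in jumps:
        if t0 >= t_end:
            raise ValueError(f"dose at t={t0} not before t_end={t_end}")
        jump_map[t0] = jump_map.get(t0, 0.0) + dy

    grid = np.arange(0.0, t_end + 0.5 * settings.grid_min, settings.grid_min)
    extra = [t for t in list(jump_map) + [t_end] if 0.0 <= t <= t_end]
    grid = np.unique(np.concatenate([grid, np.asarray(extra, dtype=float)]))

    bounds = sorted({0.0, t_end} | set(jump_map)
                    | {b for b in breakpoints if 0.0 < b < t_end})

    y = y0.astype(float).copy()
    if 0.0 in jump_map:
        y += jump_map[0.0]

    times: list[np.ndarray] = [np.array([0.0])]
    states: list[np.ndarray] = [y.copy()[None, :]]

    for ta, tb in zip(bounds, bounds[1:]):
        mask = (grid > ta) & (grid <= tb)
        t_eval = np.unique(np.concatenate([grid[mask], [tb]]))
        sol = solve_ivp(rhs, (ta, tb), y, method=settings.method,
                        rtol=settings.rtol, atol=settings.atol,
                        max_step=settings.max_step_min, t_eval=t_eval,
                        dense_output=False)
        if not sol.success:
            raise IntegrationError(
                f"solver failed in [{ta}, {tb}] min: {sol.message}")
        y = sol.y[:, -1].copy()
        seg_t, seg_y = sol.t, sol.y.T
        if tb in jump_map:
            y += jump_map[tb]
            seg_y = seg_y.copy()
            seg_y[-1] = y  # grid carries the post-dose value
        times.append(seg_t)
        states.append(seg_y)

    t_all = np.concatenate(times)
    y_all = np.vstack(states)
    # Segments share their boundary point; keep the later (post-jump) row.
    keep = np.ones(len(t_all), dtype=bool)
    keep[:-1] = np.diff(t_all) > 0
    return t_all[keep], y_all[keep]


def simulate(regimen: Regimen,
             t_end: float,
             physiology: Physiology | None = None,
             kinetics: KineticParams | None = None,
             scenario: ScenarioModifiers | None = None,
             settings: SolverSettings | None = None,
             driving: str = "outflow",
             qss_napqi: bool = False,
             ka_per_min: float | None = None) -> SimulationResult:
    """Integrate the full system from a drug-free initial state.

    Raises :class:`IntegrationError` on solver failure or if any
    concentration develops a negative excursion beyond tolerance.
    """
    settings = settings or SolverSettings()
    model = PbpkModel(physiology, kinetics, scenario, driving=driving,
                      qss_napqi=qss_napqi, ka_per_min=ka_per_min)

    events = expand_regimen(regimen)
    if events and events[-1].time_min >= t_end:
        raise ValueError("t_end must be after the last dose time")

    jumps: list[tuple[float, np.ndarray]] = []
    dose_inputs: list[tuple[float, float]] = []
    for e in events:
        moles, target = dose_to_moles(e, model.kinetics)
        dy = np.zeros(model.n_state)
        model.apply_dose(dy, moles, target)
        jumps.append((e.time_min, dy))
        dose_inputs.append((e.time_min, moles))

    t, y = _integrate_segments(model.rhs, model.initial_state(), t_end, jumps,
                               settings, model.scenario.breakpoints())

    conc = y[:, : model.n_comp]
    neg = conc.min()
    if neg < -1e4 * settings.atol:
        raise IntegrationError(
            f"negative concentration excursion {neg:.3e} mmol/L beyond tolerance")
    gsh = y[:, model.ix_gsh]
    napqi = y[:, model.ix_napqi].copy()
    cum = y[:, model.ix_cum: model.ix_cum + 5]
    depot = y[:, model.ix_depot]

    ceiling = model.gsh_normal * (1.0 + 1e-9) + 10 * settings.atol
    if gsh.max() > ceiling:
        raise IntegrationError(
            f"GSH exceeded its structural ceiling: {gsh.max():.12g} > {model.gsh_normal:.12g}")

    s = model.scenario
    traces = {
        "co_g": np.asarray(s.co_g(t), dtype=float),
        "co_s": np.asarray(s.co_s(t), dtype=float),
        "co_ox": np.asarray(s.co_ox(t), dtype=float),
        "kgen_mult": np.asarray(s.k_gen_mult(t), dtype=float),
    }
    if qss_napqi:
        co_ox = traces["co_ox"]
        for i in range(len(t)):
            rates = model.metabolic_rates(conc[i, model.i_liver], 1.0, 1.0, co_ox[i])
            napqi[i] = model.napqi_qss(rates[2], gsh[i])

    return SimulationResult(
        time=t, conc=conc, gsh=gsh, napqi=napqi, cum=cum, depot=depot,
        traces=traces, compartment_names=list(model.names),
        physiology=model.physiology, kinetics=model.kinetics,
        scenario=model.scenario, dose_inputs=dose_inputs,
    )


def simulate_one_compartment(regimen: Regimen,
                             t_end: float,
                             volume_l: float,
                             clearance_l_min: float,
                             kinetics: KineticParams | None = None,
                             settings: SolverSettings | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Single well-stirred blood pool with first-order elimination.

    The whole body collapses to one compartment of ``volume_l`` litres
    cleared at ``clearance_l_min`` L/min (e.g. renal extraction E*Q_kidney),
    so that between doses the concentration decays mono-exponentially with
    rate k = CL/V. Shares the event machinery of the full model and serves
    as its analytic cross-check.

    Returns (time grid, concentration mmol/L).
    """
    settings = settings or SolverSettings()
    kinetics = kinetics or default_kinetics()
    k = clearance_l_min / volume_l

    def rhs(t, y):
        return -k * y

    jumps = []
    for e in expand_regimen(regimen):
        if e.time_min >= t_end:
            raise ValueError("t_end must be after the last dose time")
        moles, _ = dose_to_moles(e, kinetics)
        jumps.append((e.time_min, np.array([moles / volume_l])))

    t, y = _integrate_segments(rhs, np.zeros(1), t_end, jumps, settings)
    return t, y[:, 0]
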
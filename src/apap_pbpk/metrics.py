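"""Headline quantities computed from simulation results.

These functions turn trajectories into the numbers a toxicologist asks for:
how deep the liver glutathione pool dips, whether and when it crosses the
injury threshold (30 % of normal), how much NAPQI-conjugation "demand" a
regimen generates, the quasi-steady-state GSH reduction under chronic dosing,
and threshold searches over the oxidation capacity and the regeneration rate.
``calibrate_baseline`` fixes the one free constant of the model, the normal
hepatic GSH concentration.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .core import SimulationResult, SolverSettings, simulate
from .dosing import Regimen, total_absorbed_mmol
from .parameters import (
    KineticParams,
    Physiology,
    default_kinetics,
    default_physiology,
)
from .scenarios import ScenarioModifiers, neutral_modifiers

__all__ = [
    "ToxicityAssessment",
    "RouteFractions",
    "assess_toxicity",
    "gsh_demand_auc",
    "gsh_auc",
    "gsh_auc_change_pct",
    "steady_state_reduction",
    "find_minimal_cyp_multiplier",
    "find_minimal_kgen_reduction",
    "route_fractions",
    "calibrate_baseline",
    "CalibrationError",
]

logger = logging.getLogger(__name__)


class CalibrationError(RuntimeError):
    """Raised when the baseline calibration cannot bracket its target."""


@dataclass(frozen=True)
class ToxicityAssessment:
    """Minimum GSH level and threshold-crossing summary of one run.

    Fractions are relative to the *normal* (unstressed) hepatic GSH
    concentration, the same reference for every scenario, so a run that
    starts from an alcohol- or fasting-reduced pool starts below 1.
    """

    min_gsh_fraction: float
    time_of_min: float
    toxic: bool
    first_crossing_time: float | None
    toxicity_fraction: float

    def __post_init__(self) -> None:
        assert self.toxic == (self.first_crossing_time is not None)
        assert self.toxic == (self.min_gsh_fraction < self.toxicity_fraction)


@dataclass(frozen=True)
class RouteFractions:
    """Disposition of the absorbed dose across clearance routes."""

    glucuronide: float
    sulfate: float
    oxidized: float
    renal: float
    residual: float  # still in the body at the end of the run
    cleared_warning: bool = False  # set when < 95 % of the dose was cleared

    def as_dict(self) -> dict[str, float]:
        return {
            "glucuronide": self.glucuronide,
            "sulfate": self.sulfate,
            "oxidized": self.oxidized,
            "renal": self.renal,
            "residual": self.residual,
        }


def assess_toxicity(result: SimulationResult,
                    kinetics: KineticParams | None = None) -> ToxicityAssessment:
    """Locate the GSH minimum and the first crossing of the injury threshold.

    The crossing time is refined by linear interpolation between the two
    grid points that straddle the threshold.
    """
    kinetics = kinetics or result.kinetics
    g = kinetics.gsh
    frac = result.gsh / g.gsh_normal
    i_min = int(np.argmin(frac))
    min_frac = float(frac[i_min])
    thr = g.toxicity_fraction

    crossing: float | None = None
    below = frac < thr
    if below.any():
        j = int(np.argmax(below))  # first grid point below threshold
        if j == 0:
            crossing = float(result.time[0])
        else:
            t0, t1 = result.time[j - 1], result.time[j]
            f0, f1 = frac[j - 1], frac[j]
            crossing = float(t0 + (thr - f0) / (f1 - f0) * (t1 - t0))

    return ToxicityAssessment(
        min_gsh_fraction=min_frac,
        time_of_min=float(result.time[i_min]),
        toxic=min_frac < thr,
        first_crossing_time=crossing,
        toxicity_fraction=thr,
    )


def gsh_demand_auc(result: SimulationResult, t_start: float = 0.0) -> float:
    """Cumulative NAPQI-GSH conjugation (mmol) from ``t_start`` to the end.

    This is the regimen's total demand on the glutathione detoxification
    system. ``t_start`` restricts the accounting window, e.g. to the
    quasi-steady-state part of a chronic run.
    """
    conj = result.cum_route("gsh_conjugated")
    start = float(np.interp(t_start, result.time, conj))
    return float(conj[-1] - start)


def gsh_auc(result: SimulationResult, t_start: float = 0.0) -> float:
    """Area under the liver GSH concentration curve (mmol/L . min)."""
    mask = result.time >= t_start
    return float(np.trapezoid(result.gsh[mask], result.time[mask]))


def gsh_auc_change_pct(result_a: SimulationResult, result_b: SimulationResult,
                       t_start: float = 0.0) -> float:
    """Relative change (%) in GSH exposure between two runs: 100*(AUC_a/AUC_b - 1).

    This is how the demand a regimen places on the detoxification system is
    compared across conditions: a protective change (hormesis under chronic
    dosing) leaves more GSH standing and shows up as a positive change of the
    adapted run against its non-adapted counterpart; an insult (CYP
    induction after drinking) shows up as a negative change against the
    healthy run.
    """
    return 100.0 * (gsh_auc(result_a, t_start) / gsh_auc(result_b, t_start) - 1.0)


def steady_state_reduction(result: SimulationResult,
                           window_min: float = 1440.0,
                           kinetics: KineticParams | None = None) -> float:
    """Percent reduction of mean liver GSH over the final window vs. normal.

    The mean over a full late window (default 24 h) is robust to where the
    dosing troughs fall on the grid. If the mean still drifts by more than
    1 % between the last two windows the run has not reached a periodic
    steady state and a warning is emitted.
    """
    kinetics = kinetics or result.kinetics
    t_end = result.time[-1]
    last = result.time >= t_end - window_min
    prev = (result.time >= t_end - 2 * window_min) & ~last
    mean_last = float(np.mean(result.gsh[last]))
    if prev.any():
        mean_prev = float(np.mean(result.gsh[prev]))
        if abs(mean_last - mean_prev) > 0.01 * mean_last:
            warnings.warn(
                f"GSH mean drifts {abs(mean_last / mean_prev - 1):.1%} between the "
                "last two windows; steady state may not be reached", stacklevel=2)
    return 100.0 * (1.0 - mean_last / kinetics.gsh.gsh_normal)


def _is_toxic(regimen: Regimen, scenario: ScenarioModifiers, t_end: float,
              physiology: Physiology | None, kinetics: KineticParams,
              settings: SolverSettings | None) -> ToxicityAssessment:
    res = simulate(regimen, t_end, physiology=physiology, kinetics=kinetics,
                   scenario=scenario, settings=settings)
    return assess_toxicity(res, kinetics)


def find_minimal_cyp_multiplier(regimen: Regimen,
                                scenario: ScenarioModifiers | None = None,
                                t_end: float = 7200.0,
                                physiology: Physiology | None = None,
                                kinetics: KineticParams | None = None,
                                settings: SolverSettings | None = None,
                                cap: float = 100.0,
                                tol: float = 0.5) -> float | None:
    """Smallest constant factor on the oxidation capacity that makes the
    regimen toxic (bisection to +-``tol``).

    Returns the upper bisection bound (known toxic; the bound one unit lower
    is known non-toxic). ``None`` when even ``cap`` is not toxic.
    """
    kinetics = kinetics or default_kinetics()
    scenario = scenario or neutral_modifiers()

    def toxic(m: float) -> bool:
        return _is_toxic(regimen, scenario.with_oxidation_multiplier(m), t_end,
                         physiology, kinetics, settings).toxic

    if toxic(1.0):
        return 1.0
    if not toxic(cap):
        logger.info("no toxic oxidation multiplier below cap %.1f", cap)
        return None
    lo, hi = 1.0, cap
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if toxic(mid):
            hi = mid
        else:
            lo = mid
    return hi


def find_minimal_kgen_reduction(regimen: Regimen,
                                t_end: float = 7200.0,
                                physiology: Physiology | None = None,
                                kinetics: KineticParams | None = None,
                                scenario: ScenarioModifiers | None = None,
                                settings: SolverSettings | None = None,
                                cap: int = 100) -> tuple[int, float] | None:
    """Smallest integer divisor of the GSH regeneration rate that makes the
    regimen toxic, together with the threshold-crossing time at that divisor.

    Scans f = 1, 2, ... (toxicity is monotone in the divisor). Returns
    ``None`` if no divisor up to ``cap`` is toxic.
    """
    kinetics = kinetics or default_kinetics()
    scenario = scenario or neutral_modifiers()
    for f in range(1, cap + 1):
        tox = _is_toxic(regimen, scenario, t_end, physiology,
                        kinetics.with_k_gen_scaled(1.0 / f), settings)
        if tox.toxic:
            return f, float(tox.first_crossing_time)
    logger.info("no toxic k_gen divisor below cap %d", cap)
    return None


def route_fractions(result: SimulationResult) -> RouteFractions:
    """Cumulative route fluxes normalized by the absorbed dose."""
    absorbed = result.absorbed_mmol
    if absorbed <= 0:
        return RouteFractions(0.0, 0.0, 0.0, 0.0, 0.0)
    cums = result.cum[-1, :4] / absorbed
    residual = float(result.body_burden_mmol()[-1] / absorbed)
    warn = residual > 0.05
    if warn:
        warnings.warn(f"only {1 - residual:.1%} of the dose was cleared; "
                      "route fractions reflect an incomplete run", stacklevel=2)
    return RouteFractions(*(float(x) for x in cums), residual, cleared_warning=warn)


def calibrate_baseline(target_depletion: float = 0.70,
                       dose_g: float = 15.0,
                       physiology: Physiology | None = None,
                       kinetics: KineticParams | None = None,
                       t_end: float = 2880.0,
                       bracket: tuple[float, float] = (1.0, 20.0),
                       tol: float = 1e-3,
                       settings: SolverSettings | None = None) -> float:
    """Normal hepatic GSH concentration (mmol/L) fixed by the toxicity anchor.

    Finds, by bisection, the [GSH]_N at which a single oral dose of
    ``dose_g`` grams depletes liver GSH to exactly ``1 - target_depletion``
    of normal. Depletion is monotone-decreasing in [GSH]_N (a larger pool
    buffers the same NAPQI burst), so the root is unique on the bracket.

    Raises :class:`CalibrationError` when the bracket does not straddle the
    target.
    """
    physiology = physiology or default_physiology()
    kinetics = kinetics or default_kinetics()
    regimen = Regimen.single(dose_g, route="oral")
    target_fraction = 1.0 - target_depletion

    def min_fraction(gsh_n: float) -> float:
        k = kinetics.with_gsh_normal(gsh_n)
        res = simulate(regimen, t_end, physiology=physiology, kinetics=k,
                       settings=settings)
        return assess_toxicity(res, k).min_gsh_fraction

    lo, hi = bracket
    f_lo = min_fraction(lo) - target_fraction
    f_hi = min_fraction(hi) - target_fraction
    if f_lo * f_hi > 0:
        raise CalibrationError(
            f"no sign change on bracket {bracket}: residuals {f_lo:.4f}, {f_hi:.4f}")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if (min_fraction(mid) - target_fraction) * f_lo <= 0:
            hi = mid
        else:
            lo = mid
    found = 0.5 * (lo + hi)
    logger.info("calibrated normal hepatic GSH: %.4f mmol/L", found)
    return found
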
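"""Time-dependent lifestyle scenario modifiers.

Each scenario is a set of dimensionless multiplier schedules applied to the
three hepatic pathway Vmax values (co_g, co_s, co_ox) and to the GSH
regeneration coefficient (k_gen_mult), plus a scaling of the initial hepatic
GSH concentration. All schedules are continuous piecewise-linear functions of
simulation time with constant extrapolation beyond the last breakpoint.

Clock convention: t = 0 is the start of the dosing simulation. For the
alcohol scenario, t = 0 is also the moment drinking stops, so CYP activity
starts at its induced maximum and decays back to normal, while the GSH pool
starts halved and its regeneration rate recovers over the first day.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .parameters import KineticParams, ScenarioConstants

__all__ = [
    "PiecewiseLinear",
    "ScenarioModifiers",
    "neutral_modifiers",
    "chronic_apap_schedule",
    "alcohol_schedule",
    "fasting_modifiers",
    "combined_chronic_alcohol",
    "evaluate_modifiers",
    "build_scenario",
    "SCENARIO_NAMES",
]

SCENARIO_NAMES = ("normal", "chronic", "alcohol", "fasting", "chronic+alcohol")


@dataclass(frozen=True)
class PiecewiseLinear:
    """Continuous piecewise-linear function on t >= 0.

    Defined by strictly increasing breakpoints and values; constant
    extrapolation on both sides (``np.interp`` semantics).
    """

    times: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.times) != len(self.values) or not self.times:
            raise ValueError("times and values must be equal-length, non-empty")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("breakpoints must be strictly increasing")

    def __call__(self, t):
        return np.interp(t, self.times, self.values)

    def scaled(self, factor: float) -> "PiecewiseLinear":
        """Multiply the whole schedule by a constant factor."""
        return PiecewiseLinear(self.times, tuple(v * factor for v in self.values))

    def product(self, other: "PiecewiseLinear") -> "PiecewiseLinear":
        """Pointwise product on the union of breakpoints.

        Exact whenever at most one factor varies between adjacent merged
        breakpoints (always the case for the scenario compositions here,
        where each coefficient is non-constant in at most one sub-scenario).
        """
        times = tuple(sorted(set(self.times) | set(other.times)))
        values = tuple(float(self(t) * other(t)) for t in times)
        return PiecewiseLinear(times, values)


CONSTANT_ONE = PiecewiseLinear((0.0,), (1.0,))


def _constant(v: float) -> PiecewiseLinear:
    return PiecewiseLinear((0.0,), (float(v),))


def _ramp(v0: float, v1: float, duration: float) -> PiecewiseLinear:
    return PiecewiseLinear((0.0, float(duration)), (float(v0), float(v1)))


@dataclass(frozen=True)
class ScenarioModifiers:
    """Multiplier schedules plus the GSH-pool scaling of one scenario.

    ``initial_gsh_fraction`` scales the starting hepatic GSH concentration;
    ``gsh_target_fraction`` scales the level regeneration pulls toward. A
    transient insult that resolves (alcohol) keeps the target at 1 — the pool
    returns to normal — whereas a persistent state (ongoing malnutrition)
    lowers the target itself, so the reduced pool is a true steady state.
    """

    co_g: PiecewiseLinear = CONSTANT_ONE
    co_s: PiecewiseLinear = CONSTANT_ONE
    co_ox: PiecewiseLinear = CONSTANT_ONE
    k_gen_mult: PiecewiseLinear = CONSTANT_ONE
    initial_gsh_fraction: float = 1.0
    gsh_target_fraction: float = 1.0
    name: str = "normal"

    def breakpoints(self) -> tuple[float, ...]:
        """All schedule breakpoints (useful as integrator restart points)."""
        pts: set[float] = set()
        for f in (self.co_g, self.co_s, self.co_ox, self.k_gen_mult):
            pts.update(f.times)
        return tuple(sorted(pts))

    def with_oxidation_multiplier(self, factor: float) -> "ScenarioModifiers":
        """Scale the whole oxidation schedule by a constant factor."""
        return replace(self, co_ox=self.co_ox.scaled(factor),
                       name=f"{self.name}*ox{factor:g}")


def neutral_modifiers() -> ScenarioModifiers:
    """The normal scenario: all multipliers identically 1."""
    return ScenarioModifiers()


def chronic_apap_schedule(dose_g_per_interval: float,
                          constants: ScenarioConstants | None = None) -> ScenarioModifiers:
    """Dose-dependent enzyme adaptation under chronic (6-hourly) dosing.

    Glucuronidation capacity ramps linearly from 1 up to its dose-tier
    maximum over the adaptation window (3 days) and then holds; sulfation
    capacity falls likewise to its tier minimum (cofactor depletion).
    Oxidation and GSH turnover are unaffected.
    """
    if dose_g_per_interval <= 0:
        raise ValueError("dose must be > 0")
    c = constants or ScenarioConstants()
    co_g_max, co_s_max = c.chronic_maxima(dose_g_per_interval)
    return ScenarioModifiers(
        co_g=_ramp(1.0, co_g_max, c.chronic_ramp_min),
        co_s=_ramp(1.0, co_s_max, c.chronic_ramp_min),
        name="chronic",
    )


def alcohol_schedule(constants: ScenarioConstants | None = None) -> ScenarioModifiers:
    """After-effects of a binge-drinking episode that ends at t = 0.

    CYP-mediated oxidation starts at its ethanol-induced maximum and decays
    linearly to normal over 5 days; the hepatic GSH pool starts halved, and
    its regeneration coefficient recovers from the same factor to normal over
    the first 24 h.
    """
    c = constants or ScenarioConstants()
    return ScenarioModifiers(
        co_ox=_ramp(c.alcohol_cyp_factor, 1.0, c.alcohol_cyp_ramp_min),
        k_gen_mult=_ramp(c.alcohol_gsh_fraction, 1.0, c.alcohol_gsh_ramp_min),
        initial_gsh_fraction=c.alcohol_gsh_fraction,
        name="alcohol",
    )


def fasting_modifiers(constants: ScenarioConstants | None = None) -> ScenarioModifiers:
    """Fasting/malnutrition: constant factors, no ramps.

    Glucuronidation down 40 %, sulfation down 30 %, oxidation up 50 %, the
    GSH pool down 25 % and a reduced regeneration rate. Malnutrition is a
    persistent state, so the reduced pool is also the regeneration target:
    without drug the fasting liver is stationary at 75 % of normal rather
    than drifting back up.
    """
    c = constants or ScenarioConstants()
    return ScenarioModifiers(
        co_g=_constant(c.fasting_co_g),
        co_s=_constant(c.fasting_co_s),
        co_ox=_constant(c.fasting_co_ox),
        k_gen_mult=_constant(c.fasting_k_gen_fraction),
        initial_gsh_fraction=c.fasting_gsh_fraction,
        gsh_target_fraction=c.fasting_gsh_fraction,
        name="fasting",
    )


def combined_chronic_alcohol(dose_g_per_interval: float,
                             constants: ScenarioConstants | None = None) -> ScenarioModifiers:
    """Chronic user who stops a binge-drinking episode at t = 0.

    Pointwise product of the chronic and alcohol schedules on each
    coefficient, on a shared clock; the initial GSH pool takes the alcohol
    scaling.
    """
    c = constants or ScenarioConstants()
    chronic = chronic_apap_schedule(dose_g_per_interval, c)
    alcohol = alcohol_schedule(c)
    return ScenarioModifiers(
        co_g=chronic.co_g.product(alcohol.co_g),
        co_s=chronic.co_s.product(alcohol.co_s),
        co_ox=chronic.co_ox.product(alcohol.co_ox),
        k_gen_mult=chronic.k_gen_mult.product(alcohol.k_gen_mult),
        initial_gsh_fraction=alcohol.initial_gsh_fraction,
        name="chronic+alcohol",
    )


def evaluate_modifiers(m: ScenarioModifiers, t: float) -> tuple[float, float, float, float]:
    """(co_g, co_s, co_ox, k_gen_mult) at time t (min). t < 0 is an error."""
    if np.any(np.asarray(t) < 0):
        raise ValueError("modifier schedules are defined for t >= 0")
    return (float(m.co_g(t)), float(m.co_s(t)), float(m.co_ox(t)), float(m.k_gen_mult(t)))


def build_scenario(name: str, dose_g_per_interval: float | None = None,
                   kinetics: KineticParams | None = None) -> ScenarioModifiers:
    """Construct one of the named scenarios from a kinetic parameter set.

    ``dose_g_per_interval`` selects the chronic induction tier and is
    required for the chronic scenarios.
    """
    constants = (kinetics or KineticParams()).scenario_constants
    if name == "normal":
        return neutral_modifiers()
    if name == "chronic":
        if dose_g_per_interval is None:
            raise ValueError("chronic scenario needs the per-administration dose")
        return chronic_apap_schedule(dose_g_per_interval, constants)
    if name == "alcohol":
        return alcohol_schedule(constants)
    if name == "fasting":
        return fasting_modifiers(constants)
    if name == "chronic+alcohol":
        if dose_g_per_interval is None:
            raise ValueError("chronic+alcohol scenario needs the per-administration dose")
        return combined_chronic_alcohol(dose_g_per_interval, constants)
    raise ValueError(f"unknown scenario {name!r}; valid names: {SCENARIO_NAMES}")
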
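"""Dose events and regimens.

A dose is an instantaneous bolus (Dirac input): intravenous doses enter the
venous blood pool, oral doses enter the gut tissue scaled by the oral
bioavailability F. An optional first-order absorption constant routes oral
doses through a gut-lumen depot instead (off by default; the default model
carries only a bioavailability).
"""

from __future__ import annotations

from dataclasses import dataclass

from .parameters import KineticParams

__all__ = ["DoseEvent", "Regimen", "expand_regimen", "dose_to_moles", "total_absorbed_mmol"]

ROUTES = ("iv", "oral")


@dataclass(frozen=True)
class DoseEvent:
    """A single timed administration."""

    time_min: float
    amount_g: float
    route: str = "oral"

    def __post_init__(self) -> None:
        if self.time_min < 0:
            raise ValueError(f"dose time must be >= 0 (got {self.time_min})")
        if self.amount_g < 0:
            raise ValueError(f"dose amount must be >= 0 (got {self.amount_g})")
        if self.route not in ROUTES:
            raise ValueError(f"route must be one of {ROUTES} (got {self.route!r})")


@dataclass(frozen=True)
class Regimen:
    """Either an explicit event list or a periodic specification.

    A periodic regimen of ``n_doses`` doses of ``dose_g`` every
    ``interval_min`` minutes expands to events at t = 0, T, 2T, ...,
    (n-1)T.
    """

    events: tuple[DoseEvent, ...] = ()
    dose_g: float | None = None
    interval_min: float | None = None
    n_doses: int | None = None
    route: str = "oral"

    @classmethod
    def single(cls, dose_g: float, route: str = "oral") -> "Regimen":
        return cls(events=(DoseEvent(0.0, dose_g, route),))

    @classmethod
    def periodic(cls, dose_g: float, interval_min: float, n_doses: int,
                 route: str = "oral") -> "Regimen":
        if interval_min <= 0:
            raise ValueError("interval_min must be > 0")
        if n_doses < 1:
            raise ValueError("n_doses must be >= 1")
        return cls(dose_g=dose_g, interval_min=interval_min, n_doses=n_doses, route=route)

    @property
    def is_periodic(self) -> bool:
        return self.dose_g is not None

    def last_dose_time(self) -> float:
        ev = expand_regimen(self)
        return ev[-1].time_min if ev else 0.0


def expand_regimen(regimen: Regimen) -> list[DoseEvent]:
    """Expand a regimen into a sorted explicit event list.

    Idempotent on already-explicit lists. Simultaneous events with the same
    route are merged by summing their amounts.
    """
    if regimen.is_periodic:
        if regimen.interval_min is None or regimen.n_doses is None:
            raise ValueError("periodic regimen needs dose_g, interval_min and n_doses")
        events = [
            DoseEvent(i * regimen.interval_min, regimen.dose_g, regimen.route)
            for i in range(regimen.n_doses)
        ]
        events.extend(regimen.events)
    else:
        events = list(regimen.events)

    merged: dict[tuple[float, str], float] = {}
    for e in events:
        key = (e.time_min, e.route)
        merged[key] = merged.get(key, 0.0) + e.amount_g
    return [DoseEvent(t, a, r) for (t, r), a in sorted(merged.items())]


def dose_to_moles(event: DoseEvent, kinetics: KineticParams) -> tuple[float, str]:
    """Systemically available amount (mmol) and target compartment of a dose.

    IV doses enter venous blood in full; oral doses enter the gut tissue
    scaled by the bioavailability F.

    Returns
    -------
    (mmol, target) with target ``"venous_blood"`` or ``"gut"``.
    """
    mmol = event.amount_g * 1000.0 / kinetics.apap_molar_mass
    if event.route == "iv":
        return mmol, "venous_blood"
    return mmol * kinetics.oral_bioavailability, "gut"


def total_absorbed_mmol(regimen: Regimen, kinetics: KineticParams) -> float:
    """Total systemically available input over the whole regimen (mmol)."""
    return sum(dose_to_moles(e, kinetics)[0] for e in expand_regimen(regimen))
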
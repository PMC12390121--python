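"""Exposure scenarios and the conversion of media concentrations to daily
PFOS intake.

An :class:`ExposureScenario` holds day-indexed PFOS concentrations in the
animal's forage, drinking water and ingested soil, plus the lactating dam's
feed and water (which drive the milk pathway for the nursing calf).
:func:`daily_intake` composes these with the physiology submodels into a
daily PFOS mass intake (ug/day) with a per-route breakdown.

The milk pathway is a chain: the dam's daily PFOS intake (ug/day) times the
milk transfer factor (d/kg) gives the fluid-milk concentration (ug/kg); the
calf consumes the full fluid milk production.  The dam's own body burden is
not tracked — her milk concentration responds to her current daily intake.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import physiology as phys
from .physiology import AnimalClass, IntakeParams
from .profiles import TransferParams

__all__ = [
    "ExposureScenario",
    "IntakeBreakdown",
    "cow_daily_intake",
    "milk_concentration",
    "daily_intake",
]

_MEDIA = ("forage_conc", "water_conc", "soil_conc", "cow_forage_conc", "cow_water_conc")


@dataclass(frozen=True)
class ExposureScenario:
    """Day-indexed PFOS concentrations for every exposure medium.

    Arrays all have length ``duration`` (one entry per simulated day,
    day 0 = birth).  Units: ug/kg DM for forage and soil, ug/L for water.
    ``initial_body_burden`` (ug) allows for pre-natal transfer; 0 by default.
    """

    forage_conc: np.ndarray
    water_conc: np.ndarray
    soil_conc: np.ndarray
    cow_forage_conc: np.ndarray
    cow_water_conc: np.ndarray
    initial_body_burden: float = 0.0

    def __post_init__(self) -> None:
        for name in _MEDIA:
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
        n = len(self.forage_conc)
        for name in _MEDIA:
            arr = getattr(self, name)
            if arr.ndim != 1 or len(arr) != n:
                raise ValueError(f"{name} must be 1-D of length {n}")
            if np.any(arr < 0) or np.any(~np.isfinite(arr)):
                raise ValueError(f"{name} must be finite and non-negative")
        if n < 1:
            raise ValueError("scenario must cover at least one day")
        if self.initial_body_burden < 0:
            raise ValueError("initial_body_burden must be non-negative")

    @property
    def duration(self) -> int:
        return len(self.forage_conc)

    @classmethod
    def constant(
        cls,
        duration: int,
        forage: float = 0.0,
        water: float = 0.0,
        soil: float = 0.0,
        cow_forage: float | None = None,
        cow_water: float | None = None,
        initial_body_burden: float = 0.0,
    ) -> "ExposureScenario":
        """Constant concentrations over the whole duration.  The dam's feed
        and water default to the animal's own (shared ration)."""
        full = lambda v: np.full(duration, float(v))
        return cls(
            forage_conc=full(forage),
            water_conc=full(water),
            soil_conc=full(soil),
            cow_forage_conc=full(forage if cow_forage is None else cow_forage),
            cow_water_conc=full(water if cow_water is None else cow_water),
            initial_body_burden=initial_body_burden,
        )

    @classmethod
    def from_segments(
        cls,
        segments,
        duration: int | None = None,
        initial_body_burden: float = 0.0,
    ) -> "ExposureScenario":
        """Build a scenario from piecewise-constant segments.

        ``segments`` is an iterable of mappings with keys ``start_day``,
        ``end_day`` (exclusive) and any of the media columns; unlisted media
        default to 0 and a missing ``cow_forage_conc``/``cow_water_conc``
        falls back to the animal's own forage/water concentration.
        """
        segments = list(segments)
        if duration is None:
            duration = max(int(s["end_day"]) for s in segments)
        arrays = {name: np.zeros(duration) for name in _MEDIA}
        for seg in segments:
            lo, hi = int(seg["start_day"]), int(seg["end_day"])
            if not 0 <= lo < hi <= duration:
                raise ValueError(f"segment [{lo}, {hi}) outside [0, {duration})")
            for name in _MEDIA:
                if name in seg and seg[name] is not None:
                    arrays[name][lo:hi] = float(seg[name])
            if "cow_forage_conc" not in seg and "forage_conc" in seg:
                arrays["cow_forage_conc"][lo:hi] = float(seg["forage_conc"])
            if "cow_water_conc" not in seg and "water_conc" in seg:
                arrays["cow_water_conc"][lo:hi] = float(seg["water_conc"])
        return cls(initial_body_burden=initial_body_burden, **arrays)

    def to_segments(self) -> list[dict]:
        """Compress the day-indexed arrays back to piecewise-constant
        segments (inverse of :meth:`from_segments` up to representation)."""
        stacked = np.column_stack([getattr(self, name) for name in _MEDIA])
        change = np.any(np.diff(stacked, axis=0) != 0, axis=1)
        starts = np.concatenate([[0], np.nonzero(change)[0] + 1])
        ends = np.concatenate([starts[1:], [self.duration]])
        return [
            {"start_day": int(lo), "end_day": int(hi),
             **{name: float(getattr(self, name)[lo]) for name in _MEDIA}}
            for lo, hi in zip(starts, ends)
        ]

    def scaled(self, alpha: float) -> "ExposureScenario":
        """All concentrations scaled by ``alpha`` (burden left unchanged)."""
        return ExposureScenario(
            *(getattr(self, name) * alpha for name in _MEDIA),
            initial_body_burden=self.initial_body_burden,
        )


@dataclass(frozen=True)
class IntakeBreakdown:
    """Daily PFOS intake (ug/day) split by route."""

    forage: float
    water: float
    soil: float
    milk: float

    @property
    def total(self) -> float:
        return self.forage + self.water + self.soil + self.milk


def cow_daily_intake(
    age_of_calf: int,
    scenario: ExposureScenario,
    intake_params: IntakeParams = IntakeParams(),
) -> float:
    """The lactating dam's daily PFOS intake (ug/day) at the calf's age:
    her forage DMI times her feed concentration, plus drinking water and
    incidental soil ingestion."""
    dmi = phys.cow_dmi(age_of_calf, intake_params)
    return (
        dmi * float(scenario.cow_forage_conc[age_of_calf])
        + intake_params.water_lactating_cow * float(scenario.cow_water_conc[age_of_calf])
        + intake_params.soil_fraction * dmi * float(scenario.soil_conc[age_of_calf])
    )


def milk_concentration(cow_intake: float, tp: TransferParams = TransferParams()) -> float:
    """Fluid-milk PFOS concentration (ug/kg) from the dam's daily intake
    (ug/day) via the milk transfer factor (d/kg)."""
    if cow_intake < 0:
        raise ValueError("cow_intake must be non-negative")
    return tp.milk_transfer_factor * cow_intake


def daily_intake(
    age: int,
    scenario: ExposureScenario,
    intake_params: IntakeParams = IntakeParams(),
    tp: TransferParams = TransferParams(),
) -> IntakeBreakdown:
    """The animal's total daily PFOS intake (ug/day) with route breakdown.

    Routes: forage (DMI x feed concentration), drinking water, incidental
    soil, and — before weaning — milk from the exposed dam.  All routes are
    scaled by the gut absorption fraction.
    """
    if not 0 <= age < scenario.duration:
        raise ValueError(f"age {age} outside scenario duration {scenario.duration}")
    dmi_f = phys.forage_dmi(age, intake_params)
    cls = phys.water_class_for_age(age, intake_params)
    wi = phys.water_intake(age, cls, dmi_f, intake_params)
    a = tp.absorption_fraction
    forage = a * dmi_f * float(scenario.forage_conc[age])
    water = a * wi * float(scenario.water_conc[age])
    soil = a * phys.soil_intake(dmi_f, intake_params) * float(scenario.soil_conc[age])
    milk = 0.0
    if age < intake_params.weaning_day:
        m_conc = milk_concentration(cow_daily_intake(age, scenario, intake_params), tp)
        milk = a * phys.milk_production(age, intake_params) * m_conc
    return IntakeBreakdown(forage=forage, water=water, soil=soil, milk=milk)
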
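"""Deterministic growth and intake submodels for beef cattle.

Everything here is a function of the animal's age in integer days, with day 0
at birth.  The growth curve is the derivative-summed form of an NRC-style
quartic for Holstein steers; forage dry-matter intake (DMI) follows a single
logarithmic curve fitted to combined calf and finisher intake data; milk
production is a quartic lactation curve averaged over four peak-production
levels.  Water and soil intakes are simple multiples or NRC-averaged
constants.

Units: body weight in kg, intakes in kg dry matter per day (DMI) or litres
per day (water), ages in days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "GrowthParams",
    "IntakeParams",
    "AnimalClass",
    "body_weight",
    "body_weight_curve",
    "daily_gain",
    "forage_dmi",
    "milk_production",
    "milk_dmi",
    "calf_forage_dmi_energy",
    "water_intake",
    "soil_intake",
]

#: Quartic body-weight growth curve coefficients (kg; d = age in days):
#: BW = 35.45 + 0.5584 d + 0.001787 d^2 - 1.549e-6 d^3 - 1.332e-9 d^4
BW_POLY = (35.45, 0.5584, 0.001787, -1.549e-6, -1.332e-9)

#: Derivative of the growth curve (kg/day), used as the daily weight gain.
GAIN_POLY = (0.5584, 2 * 0.001787, -3 * 1.549e-6, -4 * 1.332e-9)


class AnimalClass(str, Enum):
    """Water-intake class of the animal."""

    NURSING_CALF = "nursing_calf"
    FINISHER = "finisher"
    LACTATING_COW = "lactating_cow"


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of the body-weight model.

    ``gain_poly_coeffs`` are the four coefficients of the daily-gain
    polynomial (the derivative of the quartic growth curve), lowest order
    first.  After ``late_gain_start_day`` (540 days) a constant gain of
    ``late_gain`` kg/day is assumed.
    """

    birth_weight: float = 35.45  # kg
    gain_poly_coeffs: tuple[float, float, float, float] = GAIN_POLY
    late_gain: float = 0.32  # kg/day beyond day 540
    late_gain_start_day: int = 540
    gain_cv: float = 0.35  # relative SD multiplier on the daily gain
    late_gain_sd: float = 0.112  # kg/day
    birth_weight_sd: float = 3.27  # kg

    def __post_init__(self) -> None:
        if self.birth_weight <= 0:
            raise ValueError("birth_weight must be positive")
        if self.late_gain <= 0:
            raise ValueError("late_gain must be positive")


@dataclass(frozen=True)
class IntakeParams:
    """Parameters of the intake submodels (forage, milk, water, soil).

    Forage DMI is zero before ``dmi_start_day`` and follows
    ``dmi_log_slope * ln(d) + dmi_log_intercept`` afterwards, floored at
    zero.  The cow's DMI (for the milk-transfer pathway) is a quadratic in
    the calf's age; fluid milk production is a quartic lactation curve that
    switches off at ``weaning_day``.
    """

    dmi_log_slope: float = 5.4702  # kg per ln(day)
    dmi_log_intercept: float = -22.889  # kg
    dmi_start_day: int = 66  # forage DMI is 0 before this age
    dmi_sd_bw_fraction: float = 0.0013  # SD of forage DMI = BW * this
    cow_dmi_quad_coeffs: tuple[float, float, float] = (11.697, 0.0196, -1e-4)
    cow_dmi_cv: float = 0.062
    milk_prod_poly_coeffs: tuple[float, float, float, float, float] = (
        1.445,
        0.3024,
        -0.003686,
        0.0000163,
        -0.0000000257,
    )
    milk_prod_cv: float = 0.355
    milk_dm_fraction: float = 0.13  # fluid milk -> dry matter
    weaning_day: int = 240
    soil_fraction: float = 0.0243  # soil intake as fraction of forage DMI
    soil_fraction_sd: float = 0.005
    water_rate_calf: float = 4.0  # L per kg forage DMI
    water_finisher: float = 40.84  # L/day
    water_finisher_sd: float = 12.87
    water_lactating_cow: float = 56.47  # L/day
    water_lactating_cow_sd: float = 8.16

    def __post_init__(self) -> None:
        if not 0 < self.milk_dm_fraction < 1:
            raise ValueError("milk_dm_fraction must lie in (0, 1)")
        if not 0 <= self.soil_fraction < 0.1:
            raise ValueError("soil_fraction must lie in [0, 0.1)")
        if self.dmi_start_day >= self.weaning_day:
            raise ValueError("dmi_start_day must precede weaning_day")


def daily_gain(age: int, params: GrowthParams = GrowthParams()) -> float:
    """Daily body-weight gain (kg/day) at integer age ``age``.

    The gain polynomial (derivative of the growth quartic) applies through
    day 540; beyond that a constant finishing gain is used.
    """
    if age < 0:
        raise ValueError("age must be non-negative")
    if age > params.late_gain_start_day:
        return params.late_gain
    c0, c1, c2, c3 = params.gain_poly_coeffs
    return c0 + c1 * age + c2 * age**2 + c3 * age**3


def body_weight(age: int, params: GrowthParams = GrowthParams()) -> float:
    """Body weight (kg) at integer age ``age`` by daily summation of gains.

    Day 0 returns the birth weight; each subsequent day adds that day's
    gain, mirroring the row-per-day bookkeeping of the accumulation model.
    """
    if age < 0:
        raise ValueError("age must be non-negative")
    return float(body_weight_curve(age, params)[-1])


def body_weight_curve(max_age: int, params: GrowthParams = GrowthParams()) -> np.ndarray:
    """Body weight (kg) for every age ``0..max_age`` inclusive (vectorised)."""
    if max_age < 0:
        raise ValueError("max_age must be non-negative")
    ages = np.arange(max_age + 1)
    c0, c1, c2, c3 = params.gain_poly_coeffs
    gains = c0 + c1 * ages + c2 * ages**2 + c3 * ages**3
    gains[ages > params.late_gain_start_day] = params.late_gain
    gains[0] = 0.0  # day 0 is the birth weight itself
    return params.birth_weight + np.cumsum(gains)


def body_weight_closed_form(age: float) -> float:
    """Closed-form quartic growth curve; retained as an independent check
    on the summed-gain path."""
    c0, c1, c2, c3, c4 = BW_POLY
    return c0 + c1 * age + c2 * age**2 + c3 * age**3 + c4 * age**4


def forage_dmi(age: int, params: IntakeParams = IntakeParams()) -> float:
    """Forage dry-matter intake (kg DM/day) at integer age ``age``.

    Zero before ``dmi_start_day``; afterwards the logarithmic curve, floored
    at zero (the curve crosses zero just before day 66, so the switch is
    continuous to within ~0.03 kg).
    """
    if age < 0:
        raise ValueError("age must be non-negative")
    if age < params.dmi_start_day or age == 0:  # log curve undefined at 0
        return 0.0
    return max(0.0, params.dmi_log_slope * math.log(age) + params.dmi_log_intercept)


def milk_production(age_of_calf: int, params: IntakeParams = IntakeParams()) -> float:
    """Fluid milk production of the dam (kg/day) at the calf's age.

    A quartic lactation curve (average of four peak-production levels);
    zero at and after weaning, floored at zero inside the lactation window.
    """
    if age_of_calf < 0:
        raise ValueError("age must be non-negative")
    if age_of_calf >= params.weaning_day:
        return 0.0
    c = params.milk_prod_poly_coeffs
    d = age_of_calf
    return max(0.0, c[0] + c[1] * d + c[2] * d**2 + c[3] * d**3 + c[4] * d**4)


def milk_dmi(age: int, params: IntakeParams = IntakeParams()) -> float:
    """Dry-matter intake from milk (kg DM/day): the calf drinks all fluid
    milk produced, and fluid milk is ~13% dry matter."""
    return milk_production(age, params) * params.milk_dm_fraction


def calf_forage_dmi_energy(
    age: int,
    params: IntakeParams = IntakeParams(),
    growth: GrowthParams = GrowthParams(),
    dei: float = 0.0783,
    de_m: float = 4.87,
    de_f: float = 2.27,
) -> float:
    """Energy-balance derivation of the nursing calf's forage DMI (kg DM/day).

    DMI_F = (DEI * BW - DE_M * DMI_M) / DE_F, floored at zero, where DEI is
    the daily digestible-energy intake per kg body weight (Mcal/kg BW/day),
    DE_M the digestible energy of milk dry matter and DE_F that of forage
    (Mcal/kg).  This documents the derivation behind the combined
    birth-to-slaughter intake curve; the simulator's operative intake rule
    is :func:`forage_dmi`.
    """
    if de_f <= 0:
        raise ValueError("forage digestible energy must be positive")
    if not 0 <= age <= params.weaning_day:
        raise ValueError("energy-balance DMI is defined for nursing ages only")
    bw = body_weight(age, growth)
    dmi_m = milk_dmi(age, params)
    return max(0.0, (dei * bw - de_m * dmi_m) / de_f)


def water_intake(
    age: int,
    animal_class: AnimalClass | str,
    forage_dmi_value: float,
    params: IntakeParams = IntakeParams(),
) -> float:
    """Drinking-water intake (L/day) by animal class.

    Nursing calves drink 4 L per kg of forage DMI (milk water excluded);
    finishers and lactating cows use temperature-averaged constants.
    """
    if forage_dmi_value < 0:
        raise ValueError("forage DMI must be non-negative")
    cls = AnimalClass(animal_class)
    if cls is AnimalClass.NURSING_CALF:
        return params.water_rate_calf * forage_dmi_value
    if cls is AnimalClass.FINISHER:
        return params.water_finisher
    return params.water_lactating_cow


def water_class_for_age(age: int, params: IntakeParams = IntakeParams()) -> AnimalClass:
    """Default water-intake class: nursing calf before weaning, finisher after."""
    return AnimalClass.NURSING_CALF if age < params.weaning_day else AnimalClass.FINISHER


def soil_intake(forage_dmi_value: float, params: IntakeParams = IntakeParams()) -> float:
    """Incidental soil ingestion while grazing (kg/day), as a fixed fraction
    of forage DMI."""
    if forage_dmi_value < 0:
        raise ValueError("forage DMI must be non-negative")
    return params.soil_fraction * forage_dmi_value


def cow_dmi(age_of_calf: int, params: IntakeParams = IntakeParams()) -> float:
    """The lactating dam's forage DMI (kg DM/day) as a quadratic in the
    calf's age, floored at zero."""
    if age_of_calf < 0:
        raise ValueError("age must be non-negative")
    a0, a1, a2 = params.cow_dmi_quad_coeffs
    return max(0.0, a0 + a1 * age_of_calf + a2 * age_of_calf**2)
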
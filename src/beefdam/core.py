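"""The daily accumulation loop: one-compartment mass balance with
first-order elimination, evaluated one row per day of the animal's life.

Each day the model adds the day's dietary PFOS intake to the running body
burden and removes a first-order elimination amount

    eliminated = burden * (1 - 0.5 ** (1 / half_life)),

then converts the burden to tissue concentrations: the muscle holds a fixed
fraction of the whole-body burden (muscle:body ratio), spread over the
muscle mass (muscle fraction of body weight x body weight); serum follows
from the muscle:serum concentration ratio.  The bioaccumulation factor
(BAF) is the muscle concentration at slaughter divided by the ration
concentration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import physiology as phys
from .exposure import ExposureScenario, IntakeBreakdown, daily_intake
from .profiles import ParameterProfile, PartitionParams, default_profile

__all__ = [
    "DailyState",
    "SimulationResult",
    "daily_elimination",
    "muscle_mass_of_pfos",
    "muscle_concentration",
    "serum_concentration",
    "simulate",
    "bioaccumulation_factor",
    "solve_ration_for_target",
    "PartitionParams",
]


def daily_elimination(body_burden: float, half_life: float) -> float:
    """One day of first-order elimination (ug) from ``body_burden`` (ug) at
    the given half-life (days).  Always in ``[0, body_burden]``."""
    if half_life <= 0:
        raise ValueError("half_life must be positive")
    if body_burden < 0:
        raise ValueError("body_burden must be non-negative")
    return body_burden * (1.0 - 0.5 ** (1.0 / half_life))


def muscle_mass_of_pfos(body_burden: float, pp: PartitionParams) -> float:
    """PFOS mass in skeletal muscle (ug): muscle:body ratio x whole-body burden."""
    if body_burden < 0:
        raise ValueError("body_burden must be non-negative")
    return pp.muscle_body_ratio * body_burden


def muscle_concentration(body_burden: float, body_weight: float, pp: PartitionParams) -> float:
    """PFOS concentration in muscle (ug/kg): the muscle PFOS mass divided by
    the muscle mass (muscle fraction of BW x BW)."""
    if body_weight <= 0:
        raise ValueError("body_weight must be positive")
    return muscle_mass_of_pfos(body_burden, pp) / (pp.muscle_bw_fraction * body_weight)


def serum_concentration(muscle_conc: float, pp: PartitionParams) -> float:
    """PFOS concentration in serum (ug/kg) from the muscle concentration.

    The muscle:serum ratio is muscle conc / serum conc (0.080 by default:
    serum runs well above muscle for PFOS), so serum = muscle / ratio.
    """
    if pp.muscle_serum_ratio <= 0:
        raise ValueError("muscle_serum_ratio must be positive")
    if muscle_conc < 0:
        raise ValueError("muscle_conc must be non-negative")
    return muscle_conc / pp.muscle_serum_ratio


@dataclass(frozen=True)
class DailyState:
    """One simulated day, recorded end-of-day (after elimination)."""

    age: int  # days
    body_weight: float  # kg
    intake_forage: float  # ug
    intake_water: float  # ug
    intake_soil: float  # ug
    intake_milk: float  # ug
    intake_total: float  # ug
    eliminated: float  # ug
    body_burden: float  # ug
    muscle_conc: float  # ug/kg
    serum_conc: float  # ug/kg


@dataclass(frozen=True)
class SimulationResult:
    """Full day-by-day trajectory plus terminal summaries."""

    trajectory: list[DailyState]
    slaughter_day: int
    final_muscle_conc: float  # ug/kg
    final_serum_conc: float  # ug/kg

    @property
    def final_body_burden(self) -> float:
        return self.trajectory[-1].body_burden

    def to_dataframe(self) -> pd.DataFrame:
        """The trajectory as a tidy one-row-per-day DataFrame."""
        return pd.DataFrame([vars(s) for s in self.trajectory])


def simulate(
    scenario: ExposureScenario,
    profile: ParameterProfile | None = None,
) -> SimulationResult:
    """Run the deterministic daily accumulation model over a scenario.

    Day 0 starts from the scenario's initial body burden; every day the
    dietary intake is added and the first-order elimination subtracted
    (intake first by default — the order is a profile setting).  States are
    recorded end-of-day.
    """
    profile = profile or default_profile()
    pp = profile.partition
    duration = scenario.duration
    bw = phys.body_weight_curve(duration - 1, profile.growth)
    frac = 1.0 - 0.5 ** (1.0 / pp.half_life)
    burden = scenario.initial_body_burden
    trajectory: list[DailyState] = []
    for age in range(duration):
        routes = daily_intake(age, scenario, profile.intake, profile.transfer)
        if profile.update_order == "intake_first":
            burden += routes.total
            eliminated = burden * frac
            burden -= eliminated
        else:  # eliminate_first
            eliminated = burden * frac
            burden = burden - eliminated + routes.total
        m = muscle_concentration(burden, float(bw[age]), pp)
        trajectory.append(
            DailyState(
                age=age,
                body_weight=float(bw[age]),
                intake_forage=routes.forage,
                intake_water=routes.water,
                intake_soil=routes.soil,
                intake_milk=routes.milk,
                intake_total=routes.total,
                eliminated=eliminated,
                body_burden=burden,
                muscle_conc=m,
                serum_conc=serum_concentration(m, pp),
            )
        )
    last = trajectory[-1]
    return SimulationResult(
        trajectory=trajectory,
        slaughter_day=last.age,
        final_muscle_conc=last.muscle_conc,
        final_serum_conc=last.serum_conc,
    )


def bioaccumulation_factor(final_muscle_conc: float, ration_conc: float) -> float:
    """BAF: muscle concentration at slaughter over the ration concentration
    (both ug/kg)."""
    if ration_conc <= 0:
        raise ValueError("ration_conc must be positive")
    return final_muscle_conc / ration_conc


def solve_ration_for_target(
    target_muscle_conc: float,
    slaughter_day: int = 540,
    profile: ParameterProfile | None = None,
) -> float:
    """Ration concentration (ug/kg) whose deterministic simulation reaches
    ``target_muscle_conc`` in muscle at slaughter.

    With zero initial burden the model is linear in the exposure
    concentrations, so the answer is ``target / response-to-unit-ration``;
    the result is verified by re-simulation.
    """
    if target_muscle_conc <= 0:
        raise ValueError("target_muscle_conc must be positive")
    from .scenarios import GenericScenarioSpec, build_generic  # cycle-breaking import

    profile = profile or default_profile()
    unit = build_generic(GenericScenarioSpec(ration_conc=1.0, slaughter_day=slaughter_day))
    response = simulate(unit, profile).final_muscle_conc
    if response <= 0:
        raise ValueError("unit-ration response is zero; cannot invert")
    ration = target_muscle_conc / response
    check = simulate(unit.scaled(ration), profile).final_muscle_conc
    if abs(check - target_muscle_conc) > 1e-6 * target_muscle_conc:
        raise RuntimeError("linearity verification failed in solve_ration_for_target")
    return ration
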
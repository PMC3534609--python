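"""Energy-expenditure accounting: REE, AEE, TEE and net energy intake.

Total energy expenditure (TEE) is split into resting energy expenditure
(REE), obtained by indirect calorimetry from resting oxygen consumption,
and activity energy expenditure (AEE), here the walking programme of the
Minnesota starvation study (22 miles/week outdoors plus a weekly 30-minute
treadmill walk).  Net energy intake — the forcing term l(t) of the weight
recursion — is food intake minus TEE.

Walking costs are tabulated for a 54-kg reference subject and scale
linearly with body weight.  Caloric equivalents of oxygen (kcal per litre)
depend on the respiratory quotient and must be supplied by the caller from
standard indirect-calorimetry tables; no table is bundled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

__all__ = [
    "CC_PER_MIN_TO_L_PER_DAY",
    "RestingMeasurement",
    "ActivityProfile",
    "resting_ee",
    "walking_ee",
    "treadmill_ee",
    "total_ee",
    "net_energy_intake",
]

#: converts cc O2/min to litres O2/day: 1440 min/day ÷ 1000 cc/L
CC_PER_MIN_TO_L_PER_DAY = 1440 / 1000


@dataclass(frozen=True)
class RestingMeasurement:
    """Resting oxygen uptake (cc O₂/min) and its caloric equivalent (kcal/L)."""

    oxygen_consumption: float
    caloric_equivalent: float

    def __post_init__(self) -> None:
        if not self.oxygen_consumption > 0:
            raise ValueError("oxygen_consumption must be > 0")
        if not self.caloric_equivalent > 0:
            raise ValueError("caloric_equivalent must be > 0")


@dataclass(frozen=True)
class ActivityProfile:
    """Walking programme of one subject or group.

    Defaults mirror the study: 22 miles/week outdoors at 3 mph costing
    3.6 kcal/min at the 54-kg reference weight, plus 30 min/week on a
    treadmill at 4.2 kcal/min.
    """

    body_weight: float
    reference_weight: float = 54.0
    outdoor_miles_per_week: float = 22.0
    outdoor_speed: float = 3.0
    outdoor_cost: float = 3.6
    treadmill_cost: float = 4.2
    treadmill_minutes_per_week: float = 30.0

    def __post_init__(self) -> None:
        for name in (
            "body_weight",
            "reference_weight",
            "outdoor_miles_per_week",
            "outdoor_speed",
            "outdoor_cost",
            "treadmill_cost",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.treadmill_minutes_per_week < 0:
            raise ValueError("treadmill_minutes_per_week must be >= 0")

    @property
    def daily_miles(self) -> float:
        """Daily outdoor mileage, quoted to hundredths of a mile.

        The study logs express the 22 weekly miles as 3.14 miles/day; the
        hundredth-of-a-mile rounding is kept so the accounting reproduces
        the study's own arithmetic.
        """
        return round(self.outdoor_miles_per_week / 7, 2)


def resting_ee(m: RestingMeasurement) -> float:
    """REE (kcal/day) = O₂ uptake (cc/min) × 1.44 × caloric equivalent.

    The 1.44 converts cc/min to litres/day (1440 min/day ÷ 1000 cc/L).
    """
    return m.oxygen_consumption * CC_PER_MIN_TO_L_PER_DAY * m.caloric_equivalent


def walking_ee(a: ActivityProfile) -> float:
    """Daily cost of the outdoor walking programme (kcal/day).

    (weight / reference) × (daily miles / speed, h/day) × cost (kcal/min) × 60.
    """
    hours_per_day = a.daily_miles / a.outdoor_speed
    return (a.body_weight / a.reference_weight) * hours_per_day * a.outdoor_cost * 60.0


def treadmill_ee(a: ActivityProfile) -> float:
    """Daily cost of the weekly treadmill walk (kcal/day).

    (weight / reference) × cost (kcal/min) × weekly minutes / 7.
    """
    return (
        (a.body_weight / a.reference_weight)
        * a.treadmill_cost
        * a.treadmill_minutes_per_week
        / 7.0
    )


def total_ee(ree: float, aee_components: Iterable[float] = ()) -> float:
    """TEE (kcal/day) = REE + sum of activity components."""
    components = list(aee_components)
    if ree < 0 or any(c < 0 for c in components):
        raise ValueError("energy-expenditure components must be >= 0")
    return ree + sum(components)


def net_energy_intake(intake: float, tee: float) -> float:
    """Net energy intake (kcal/day) = food intake − TEE; negative in deficit."""
    return intake - tee
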
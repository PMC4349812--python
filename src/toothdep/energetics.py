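"""Orca energetics: daily toothfish requirement and depredation coverage.

The model is deliberately minimal: a fixed daily toothfish biomass
requirement per sex (100 kg/day for females, 124 kg/day for males), the
energy density of raw toothfish (184 kcal per 100 g) for unit conversion,
and the fraction of a pod's sex-weighted daily requirement covered by a
given depredated biomass.  Whether depredation can sustain a population then
depends on population size and total depredated catch, which are inputs
here, not assumptions.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

__all__ = [
    "Sex",
    "EnergeticsParams",
    "daily_requirement_kg",
    "kcal_from_kg",
    "kg_from_kcal",
    "coverage_fraction",
    "per_orca_take",
]


class Sex(enum.Enum):
    FEMALE = "female"
    MALE = "male"


@dataclass(frozen=True)
class EnergeticsParams:
    requirement_kg_day_female: float = 100.0
    requirement_kg_day_male: float = 124.0
    energy_density_kcal_per_100g: float = 184.0

    def __post_init__(self) -> None:
        if (
            self.requirement_kg_day_female <= 0
            or self.requirement_kg_day_male <= 0
            or self.energy_density_kcal_per_100g <= 0
        ):
            raise ValueError("energetics parameters must be strictly positive")


DEFAULT_PARAMS = EnergeticsParams()


def daily_requirement_kg(sex: Sex, params: EnergeticsParams = DEFAULT_PARAMS) -> float:
    """Daily toothfish biomass requirement (kg/day) for one orca of the
    given sex."""
    if sex is Sex.FEMALE:
        return params.requirement_kg_day_female
    if sex is Sex.MALE:
        return params.requirement_kg_day_male
    raise ValueError(f"unknown sex: {sex!r}")


def kcal_from_kg(mass_kg: float, params: EnergeticsParams = DEFAULT_PARAMS) -> float:
    """Energy (kcal) in a raw toothfish mass; 1 kg = 10 x 100 g portions."""
    if mass_kg < 0:
        raise ValueError("mass must be >= 0")
    return mass_kg * 10.0 * params.energy_density_kcal_per_100g


def kg_from_kcal(kcal: float, params: EnergeticsParams = DEFAULT_PARAMS) -> float:
    """Inverse of :func:`kcal_from_kg`."""
    if kcal < 0:
        raise ValueError("energy must be >= 0")
    return kcal / (10.0 * params.energy_density_kcal_per_100g)


def coverage_fraction(
    depredated_kg_per_orca_day: float,
    fraction_female: float = 1.0,
    params: EnergeticsParams = DEFAULT_PARAMS,
) -> float:
    """Fraction of the sex-weighted daily requirement met by the depredated
    biomass per orca per day; may exceed 1."""
    if depredated_kg_per_orca_day < 0:
        raise ValueError("depredated mass must be >= 0")
    if not 0.0 <= fraction_female <= 1.0:
        raise ValueError("fraction_female must be in [0, 1]")
    requirement = (
        fraction_female * params.requirement_kg_day_female
        + (1.0 - fraction_female) * params.requirement_kg_day_male
    )
    if requirement <= 0:
        raise ValueError("weighted requirement must be positive")
    return depredated_kg_per_orca_day / requirement


def per_orca_take(depredated_kg_per_line: float, orcas_at_line: int) -> float:
    """Depredated mass per orca for one line, for comparison against the
    daily requirement."""
    if orcas_at_line < 1:
        raise ValueError("orcas_at_line must be >= 1")
    if depredated_kg_per_line < 0:
        raise ValueError("depredated mass must be >= 0")
    return depredated_kg_per_line / orcas_at_line
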
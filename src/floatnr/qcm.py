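"""Analytic quartz-crystal-microbalance (QCM-D) support calculations.

QCM-D senses mass coupled to the sensor within the evanescent shear wave
the crystal launches into the liquid.  The penetration depth of that wave,

    δ = sqrt(η / (π ρ f₀ n)),

sets the depth sensitivity per overtone n, and the Sauerbrey relation maps
areal mass to the overtone-normalized frequency shift for thin rigid films.
These two formulas underpin the depth-sensitivity argument for floating
membranes sitting tens of nanometres from the sensor surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "SensorSpec",
    "FluidSpec",
    "WATER_38C",
    "penetration_depth",
    "sauerbrey_shift",
    "depth_table",
]


@dataclass(frozen=True)
class SensorSpec:
    """A QCM sensor crystal: fundamental frequency and mass sensitivity."""

    fundamental_frequency: float = 5e6  # Hz
    overtone: int = 3  # odd harmonic number
    mass_sensitivity_constant: float = 17.7  # ng·cm⁻²·Hz⁻¹ at 5 MHz

    def __post_init__(self):
        if self.overtone < 1 or self.overtone % 2 == 0:
            raise ValueError(f"overtone must be an odd integer >= 1, got {self.overtone}")
        if self.fundamental_frequency <= 0:
            raise ValueError("fundamental frequency must be positive")


@dataclass(frozen=True)
class FluidSpec:
    """Newtonian fluid above the sensor: viscosity [Pa·s], density [kg·m⁻³]."""

    viscosity: float
    density: float
    label: str = ""

    def __post_init__(self):
        if self.viscosity <= 0 or self.density <= 0:
            raise ValueError("viscosity and density must be positive")


#: pure water at 38 °C (standard property tables)
WATER_38C = FluidSpec(viscosity=6.81e-4, density=992.6, label="water 38C")


def penetration_depth(sensor: SensorSpec, fluid: FluidSpec = WATER_38C) -> float:
    """Shear-wave penetration depth δ [nm] at the sensor's overtone."""
    f = sensor.fundamental_frequency * sensor.overtone
    delta_m = math.sqrt(fluid.viscosity / (math.pi * fluid.density * f))
    return delta_m * 1e9


def sauerbrey_shift(areal_mass: float, sensor: SensorSpec = SensorSpec()) -> float:
    """Overtone-normalized frequency shift Δf_n [Hz] for a rigid areal mass.

    ``areal_mass`` in ng·cm⁻²; mass loading gives a negative shift.
    """
    if areal_mass < 0:
        raise ValueError("areal mass must be >= 0")
    return -areal_mass / sensor.mass_sensitivity_constant


def depth_table(
    overtones=(3, 5, 7),
    fundamental_frequency: float = 5e6,
    fluid: FluidSpec = WATER_38C,
) -> str:
    """Formatted table of overtone, resonance frequency and δ."""
    lines = ["overtone\tfrequency_MHz\tpenetration_depth_nm"]
    for n in overtones:
        s = SensorSpec(fundamental_frequency=fundamental_frequency, overtone=n)
        lines.append(
            f"{n}\t{fundamental_frequency * n / 1e6:.1f}"
            f"\t{penetration_depth(s, fluid):.0f}"
        )
    return "\n".join(lines)
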
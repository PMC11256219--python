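"""Scattering-length-density bookkeeping for components and solvent contrasts.

Every SLD in this package is a *nuclear* coherent scattering length density
in units of 1e-6 Å⁻² (the convention printed in reflectometry tables).
Solvent isotopic contrast is expressed as the D2O volume fraction of the
aqueous phase; materials carrying labile hydrogens exchange with the solvent
and therefore have distinct SLDs in pure H2O and pure D2O.  Exchange is
modelled as complete and linear in the D2O fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "H2O_SLD",
    "D2O_SLD",
    "Material",
    "SolventContrast",
    "NAMED_CONTRASTS",
    "DEFAULT_MATERIALS",
    "water_sld",
    "material_sld",
    "layer_sld",
]

# Pure-water endpoint SLDs, 1e-6 Å⁻².  H2O from Σb/V with b_H = -3.739 fm,
# b_O = 5.803 fm, V = 30.0 Å³; D2O is the standard tabulated value
# (b_D = 6.671 fm with the slightly larger D2O molecular volume).
H2O_SLD = -0.56
D2O_SLD = 6.36


@dataclass(frozen=True)
class Material:
    """A chemical component with solvent-dependent SLD.

    ``sld_d2o`` defaults to ``sld_h2o`` (non-exchanging material such as a
    metal, silicon, or lipid tails).
    """

    name: str
    sld_h2o: float
    sld_d2o: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.sld_h2o):
            raise ValueError(f"{self.name}: SLD must be finite")
        if self.sld_d2o is None:
            object.__setattr__(self, "sld_d2o", self.sld_h2o)
        elif not math.isfinite(self.sld_d2o):
            raise ValueError(f"{self.name}: SLD must be finite")

    @property
    def exchanging(self) -> bool:
        return self.sld_h2o != self.sld_d2o


@dataclass(frozen=True)
class SolventContrast:
    """An aqueous solvent defined by its D2O volume fraction."""

    name: str
    d2o_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.d2o_fraction <= 1.0:
            raise ValueError(
                f"d2o_fraction must be in [0, 1], got {self.d2o_fraction}"
            )

    @classmethod
    def from_name(cls, name: str) -> "SolventContrast":
        try:
            return NAMED_CONTRASTS[name]
        except KeyError:
            raise KeyError(
                f"unknown contrast {name!r}; known: {sorted(NAMED_CONTRASTS)}"
            ) from None

    @property
    def sld(self) -> float:
        return water_sld(self.d2o_fraction)


#: The four solution contrasts used in the experiments: pure D2O, gold
#: matched water (75% v/v D2O), protein matched water (42% v/v D2O), pure H2O.
NAMED_CONTRASTS = {
    "D2O": SolventContrast("D2O", 1.0),
    "AuMW": SolventContrast("AuMW", 0.75),
    "PrMW": SolventContrast("PrMW", 0.42),
    "H2O": SolventContrast("H2O", 0.0),
}


def water_sld(
    d2o_fraction: float, h2o_sld: float = H2O_SLD, d2o_sld: float = D2O_SLD
) -> float:
    """SLD of an H2O/D2O mixture, linear in the D2O volume fraction."""
    if not 0.0 <= d2o_fraction <= 1.0:
        raise ValueError(f"d2o_fraction must be in [0, 1], got {d2o_fraction}")
    return h2o_sld + d2o_fraction * (d2o_sld - h2o_sld)


def material_sld(material: Material, contrast: SolventContrast) -> float:
    """SLD of a material at a given contrast (linear labile-H exchange)."""
    f = contrast.d2o_fraction
    return material.sld_h2o + f * (material.sld_d2o - material.sld_h2o)


def layer_sld(
    composition: Sequence[tuple[Material, float]],
    contrast: SolventContrast,
    tol: float = 1e-9,
) -> float:
    """Volume-fraction-weighted SLD of a layer; solvent fills the remainder.

    ``composition`` is a list of ``(material, volume_fraction)``; fractions
    must be non-negative and sum to at most 1 (occupancy cannot exceed 100%).
    """
    total = 0.0
    sld = 0.0
    for mat, frac in composition:
        if frac < -tol:
            raise ValueError(f"negative volume fraction for {mat.name}: {frac}")
        total += frac
        sld += frac * material_sld(mat, contrast)
    if total > 1.0 + tol:
        raise ValueError(
            f"component volume fractions sum to {total:.6f} > 1"
        )
    return sld + (1.0 - total) * contrast.sld


# Default component SLD table (1e-6 Å⁻²).  Conventional literature values;
# all user-overridable through the config.
DEFAULT_MATERIALS: dict[str, Material] = {
    m.name: m
    for m in [
        Material("silicon", 2.07),
        Material("sio2", 3.47),
        Material("permalloy", 8.5),
        Material("gold", 4.5),
        # carboxyl-terminated OEG SAM: partial carboxyl H/D exchange
        Material("sam", 0.3, 0.6),
        Material("tails", -0.4),
        Material("heads", 1.85, 1.92),  # PC/PS headgroups
        Material("protein", 1.9, 3.2),  # hydrogenous protein
    ]
}
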
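"""Parameterization of the interfacial structure and its rendered forms.

The structure is, moving from the silicon substrate toward bulk solution:

    Si | SiO2–permalloy mix | permalloy | gold | COOH-OEG-SAM |
       [ solution interlayer | inner protein | inner heads | tails |
         outer heads | peripheral protein ] | solvent

The bracketed part is the floating protein–lipid membrane and is absent for
the bare-surface model.  Every layer is described by a thickness, a set of
component volume fractions (solvent filling the remainder) and the Gaussian
roughness of its top, solution-side interface.  The same description is
rendered three ways: as kernel slabs for a given solvent contrast, as a
contrast-independent component volume-fraction profile on a 1 Å grid
(erf-edged boxcars, water = unoccupied volume), and as an SLD profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.special import erf

from .kernel import QGrid, Slab, abeles_reflectivity, apply_scale_background, smear_fixed_dlogq
from .materials import (
    DEFAULT_MATERIALS,
    Material,
    SolventContrast,
    layer_sld,
    material_sld,
)

__all__ = [
    "Parameter",
    "Underlayers",
    "FloatingMembraneModel",
    "VolumeFractionProfile",
    "render_slabs",
    "component_profile",
    "sld_profile",
    "membrane_to_sam_distance",
    "model_reflectivity",
]


class Parameter:
    """A named model parameter with bounds, a vary flag and optional sharing.

    Sharing across datasets is by object identity: models that must share a
    parameter hold a reference to the same ``Parameter`` instance.  The
    ``shared_group`` label is only carried for reporting/config round-trips.
    """

    __slots__ = ("name", "_value", "bounds", "vary", "shared_group")

    def __init__(self, name, value, bounds=None, vary=False, shared_group=None):
        self.name = str(name)
        self.bounds = (
            (-math.inf, math.inf) if bounds is None else (float(bounds[0]), float(bounds[1]))
        )
        if self.bounds[0] > self.bounds[1]:
            raise ValueError(f"{name}: lower bound exceeds upper bound")
        self.vary = bool(vary)
        self.shared_group = shared_group
        self._value = None
        self.value = value

    @property
    def value(self):
        return self._value

    @value.setter
    def value(self, v):
        v = float(v)
        if not (self.bounds[0] <= v <= self.bounds[1]):
            raise ValueError(
                f"{self.name}: value {v} outside bounds {self.bounds}"
            )
        self._value = v

    def __float__(self):
        return self._value

    def __repr__(self):
        flag = "vary" if self.vary else "fixed"
        return f"Parameter({self.name}={self._value:g}, {flag}, bounds={self.bounds})"


def _as_param(name, x, bounds=None, vary=False):
    if isinstance(x, Parameter):
        return x
    return Parameter(name, x, bounds=bounds, vary=vary)


@dataclass(eq=False)
class Underlayers:
    """The solid layers between the silicon substrate and the solution.

    Thicknesses and roughnesses in Å; fractions dimensionless in [0, 1].
    These layers are shared between bare-surface and membrane datasets and
    across all solvent contrasts.
    """

    substrate_roughness: Parameter = None
    mix_thickness: Parameter = None
    mix_permalloy_fraction: Parameter = None
    mix_roughness: Parameter = None
    permalloy_thickness: Parameter = None
    permalloy_roughness: Parameter = None
    gold_thickness: Parameter = None
    gold_roughness: Parameter = None
    sam_thickness: Parameter = None
    sam_coverage: Parameter = None
    sam_roughness: Parameter = None

    def __post_init__(self):
        defaults = dict(
            substrate_roughness=(3.0, (0, 10)),
            mix_thickness=(10.0, (0, 40)),
            mix_permalloy_fraction=(0.5, (0, 1)),
            mix_roughness=(3.0, (0, 15)),
            permalloy_thickness=(150.0, (50, 300)),
            permalloy_roughness=(5.0, (0, 15)),
            gold_thickness=(100.0, (30, 200)),
            gold_roughness=(5.0, (0, 15)),
            sam_thickness=(25.0, (10, 40)),
            sam_coverage=(0.92, (0.5, 1.0)),
            sam_roughness=(9.0, (0, 20)),
        )
        for name, (value, bounds) in defaults.items():
            current = getattr(self, name)
            if current is None:
                setattr(self, name, Parameter(name, value, bounds=bounds))
            else:
                setattr(self, name, _as_param(name, current, bounds=bounds))

    def layers(self):
        """Rows of (name, thickness, {component: fraction}, top roughness)."""
        f = self.mix_permalloy_fraction.value
        return [
            ("sio2_permalloy_mix", self.mix_thickness.value,
             {"permalloy": f, "sio2": 1.0 - f}, self.mix_roughness.value),
            ("permalloy", self.permalloy_thickness.value,
             {"permalloy": 1.0}, self.permalloy_roughness.value),
            ("gold", self.gold_thickness.value,
             {"gold": 1.0}, self.gold_roughness.value),
            ("sam", self.sam_thickness.value,
             {"sam": self.sam_coverage.value}, self.sam_roughness.value),
        ]

    def parameters(self):
        return [getattr(self, f.name) for f in self.__dataclass_fields__.values()]


@dataclass(eq=False)
class FloatingMembraneModel:
    """The floating protein–lipid membrane above the SAM.

    Layer sequence (bottom to top): pure-solvent interlayer, optional inner
    protein layer (protein + water only), inner headgroups, lipid tails,
    outer headgroups, peripheral protein.  Inner and outer headgroups are
    constrained symmetric (same thickness and composition) unless
    ``symmetric_heads`` is False.  A single ``bilayer_roughness`` applies to
    all membrane-internal interfaces; the peripheral layer's outer interface
    carries its own roughness.  In each layer lipid + protein ≤ 1, with
    solvent filling the remainder.
    """

    interlayer_thickness: Parameter = None
    inner_protein_thickness: Parameter = None
    inner_protein_fraction: Parameter = None
    head_thickness: Parameter = None
    head_lipid_fraction: Parameter = None
    head_protein_fraction: Parameter = None
    tails_thickness: Parameter = None
    tails_lipid_fraction: Parameter = None
    tails_protein_fraction: Parameter = None
    outer_head_thickness: Parameter = None
    outer_head_lipid_fraction: Parameter = None
    outer_head_protein_fraction: Parameter = None
    peripheral_thickness: Parameter = None
    peripheral_protein_fraction: Parameter = None
    peripheral_roughness: Parameter = None
    bilayer_roughness: Parameter = None
    symmetric_heads: bool = True

    def __post_init__(self):
        defaults = dict(
            interlayer_thickness=(11.0, (0, 250)),
            inner_protein_thickness=(0.0, (0, 60)),
            inner_protein_fraction=(0.0, (0, 1)),
            head_thickness=(8.0, (4, 15)),
            head_lipid_fraction=(0.42, (0, 1)),
            head_protein_fraction=(0.24, (0, 1)),
            tails_thickness=(30.0, (15, 45)),
            tails_lipid_fraction=(0.61, (0, 1)),
            tails_protein_fraction=(0.24, (0, 1)),
            outer_head_thickness=(8.0, (4, 15)),
            outer_head_lipid_fraction=(0.42, (0, 1)),
            outer_head_protein_fraction=(0.24, (0, 1)),
            peripheral_thickness=(50.5, (10, 100)),
            peripheral_protein_fraction=(0.13, (0, 1)),
            peripheral_roughness=(16.5, (0, 40)),
            bilayer_roughness=(7.0, (0, 100)),
        )
        for name, (value, bounds) in defaults.items():
            current = getattr(self, name)
            if current is None:
                setattr(self, name, Parameter(name, value, bounds=bounds))
            else:
                setattr(self, name, _as_param(name, current, bounds=bounds))
        if self.symmetric_heads:
            self.outer_head_thickness = self.head_thickness
            self.outer_head_lipid_fraction = self.head_lipid_fraction
            self.outer_head_protein_fraction = self.head_protein_fraction

    def layers(self):
        """Rows of (name, thickness, {component: fraction}, top roughness).

        Zero-thickness layers (the optional inner protein distribution by
        default) are omitted.
        """
        sigma_b = self.bilayer_roughness.value
        rows = [
            ("interlayer", self.interlayer_thickness.value, {}, sigma_b),
            ("inner_protein", self.inner_protein_thickness.value,
             {"protein": self.inner_protein_fraction.value}, sigma_b),
            ("inner_heads", self.head_thickness.value,
             {"heads": self.head_lipid_fraction.value,
              "protein": self.head_protein_fraction.value}, sigma_b),
            ("tails", self.tails_thickness.value,
             {"tails": self.tails_lipid_fraction.value,
              "protein": self.tails_protein_fraction.value}, sigma_b),
            ("outer_heads", self.outer_head_thickness.value,
             {"heads": self.outer_head_lipid_fraction.value,
              "protein": self.outer_head_protein_fraction.value}, sigma_b),
            ("peripheral_protein", self.peripheral_thickness.value,
             {"protein": self.peripheral_protein_fraction.value},
             self.peripheral_roughness.value),
        ]
        return [r for r in rows if r[1] > 0.0]

    def parameters(self):
        seen, out = set(), []
        for f in self.__dataclass_fields__.values():
            p = getattr(self, f.name)
            if isinstance(p, Parameter) and id(p) not in seen:
                seen.add(id(p))
                out.append(p)
        return out


def _all_layers(underlayers: Underlayers,
                membrane: FloatingMembraneModel | None):
    rows = underlayers.layers()
    if membrane is not None:
        rows += membrane.layers()
    return rows


def render_slabs(
    underlayers: Underlayers,
    membrane: FloatingMembraneModel | None,
    contrast: SolventContrast,
    materials: Mapping[str, Material] = DEFAULT_MATERIALS,
) -> list[Slab]:
    """Render the model as an ordered slab stack at the given contrast.

    The stack runs fronting → backing: semi-infinite silicon, the solid
    under-layers, the membrane layers when present, and semi-infinite
    solvent.  Layer SLDs are composition-weighted with solvent filling
    unoccupied volume.
    """
    slabs = [
        Slab(0.0, materials["silicon"].sld_h2o,
             underlayers.substrate_roughness.value, name="silicon")
    ]
    for name, thickness, comps, rough in _all_layers(underlayers, membrane):
        sld = layer_sld(
            [(materials[c], frac) for c, frac in comps.items()], contrast
        )
        slabs.append(Slab(thickness, sld, rough, name=name))
    slabs.append(Slab(0.0, contrast.sld, 0.0, name="solvent"))
    return slabs


@dataclass
class VolumeFractionProfile:
    """Component volume fractions on a z grid (Å), water = unoccupied volume."""

    z: np.ndarray
    fractions: dict[str, np.ndarray]

    def total(self) -> np.ndarray:
        return np.sum(list(self.fractions.values()), axis=0)

    def grouped(self) -> dict[str, np.ndarray]:
        """Collapse to the headline components: substrate, SAM, lipid, protein, water."""
        g = {
            "substrate": 0.0, "sam": 0.0, "lipid": 0.0,
            "protein": 0.0, "water": 0.0,
        }
        groups = {
            "silicon": "substrate", "sio2": "substrate",
            "permalloy": "substrate", "gold": "substrate",
            "sam": "sam", "heads": "lipid", "tails": "lipid",
            "protein": "protein", "water": "water",
        }
        for name, f in self.fractions.items():
            g[groups.get(name, name)] = g.get(groups.get(name, name), 0.0) + f
        return {k: np.asarray(v) for k, v in g.items()}

    def to_tsv(self, path) -> None:
        names = list(self.fractions)
        header = (
            "component volume fractions vs distance; z in Angstrom, "
            "fractions dimensionless\nz\t" + "\t".join(names)
        )
        data = np.column_stack([self.z] + [self.fractions[n] for n in names])
        np.savetxt(path, data, header=header, delimiter="\t", fmt="%.6g")


def _edge(z, z0, sigma):
    """Rising erf edge 0→1 centred at z0 with Gaussian width sigma."""
    if sigma > 0:
        return 0.5 * (1.0 + erf((z - z0) / (np.sqrt(2.0) * sigma)))
    return (z >= z0).astype(float)


def component_profile(
    underlayers: Underlayers,
    membrane: FloatingMembraneModel | None = None,
    dz: float = 1.0,
    z: np.ndarray | None = None,
    n_sigma: float = 4.0,
    tol: float = 1e-9,
) -> VolumeFractionProfile:
    """Component volume-fraction profile: erf-edged boxcars on a 1 Å grid.

    Each layer contributes, for each of its components, a boxcar between its
    bottom and top interfaces whose edges are broadened by the corresponding
    interface roughnesses.  Water is the unoccupied volume, so the fractions
    sum to one at every grid point.  The grid extends ``n_sigma`` × roughness
    past the outermost interface unless ``z`` is given explicitly.
    """
    rows = _all_layers(underlayers, membrane)
    # interface positions: z=0 at the Si surface
    edges = np.concatenate([[0.0], np.cumsum([r[1] for r in rows])])
    sigmas = np.concatenate(
        [[underlayers.substrate_roughness.value], [r[3] for r in rows]]
    )
    if z is None:
        lo = -n_sigma * max(sigmas[0], 1.0)
        hi = edges[-1] + n_sigma * max(sigmas[-1], 1.0)
        n = int(np.ceil((hi - lo) / dz))
        z = lo + dz * (np.arange(n) + 0.5)
    else:
        z = np.asarray(z, dtype=float)

    fractions: dict[str, np.ndarray] = {"silicon": 1.0 - _edge(z, 0.0, sigmas[0])}
    for i, (name, thickness, comps, rough) in enumerate(rows):
        total = sum(comps.values())
        if total > 1.0 + 1e-9:
            raise ValueError(f"{name}: component fractions sum to {total} > 1")
        box = _edge(z, edges[i], sigmas[i]) - _edge(z, edges[i + 1], sigmas[i + 1])
        for comp, frac in comps.items():
            if frac <= 0:
                continue
            fractions[comp] = fractions.get(comp, 0.0) + frac * box
    occupied = np.sum(list(fractions.values()), axis=0)
    # erf tails of a very rough edge can reach back into an already-full
    # region; occupancy saturates at 100% by proportional rescaling there
    over = occupied > 1.0
    if np.any(over):
        scale = np.where(over, 1.0 / occupied, 1.0)
        for name in fractions:
            fractions[name] = fractions[name] * scale
        occupied = np.minimum(occupied, 1.0)
    fractions["water"] = np.clip(1.0 - occupied, 0.0, None)
    return VolumeFractionProfile(z=z, fractions=fractions)


def sld_profile(
    underlayers: Underlayers,
    membrane: FloatingMembraneModel | None,
    contrast: SolventContrast,
    materials: Mapping[str, Material] = DEFAULT_MATERIALS,
    dz: float = 1.0,
    z: np.ndarray | None = None,
):
    """SLD depth profile (z, rho): Σ_components fraction·SLD at the contrast."""
    prof = component_profile(underlayers, membrane, dz=dz, z=z)
    rho = np.zeros_like(prof.z)
    for name, frac in prof.fractions.items():
        if name == "water":
            rho += frac * contrast.sld
        else:
            rho += frac * material_sld(materials[name], contrast)
    return prof.z, rho


def membrane_to_sam_distance(membrane: FloatingMembraneModel | None) -> float:
    """Thickness of the pure-solvent gap between SAM and inner headgroups [Å]."""
    if membrane is None:
        raise ValueError("bare-surface model has no membrane-to-SAM distance")
    return membrane.interlayer_thickness.value


def model_reflectivity(
    underlayers: Underlayers,
    membrane: FloatingMembraneModel | None,
    contrast: SolventContrast,
    q: QGrid,
    scale: float = 1.0,
    background: float = 0.0,
    materials: Mapping[str, Material] = DEFAULT_MATERIALS,
    roughness_model: str = "auto",
    dz: float = 1.0,
) -> np.ndarray:
    """Smeared, scaled model reflectivity on a dataset's Q grid."""
    slabs = render_slabs(underlayers, membrane, contrast, materials)
    raw = smear_fixed_dlogq(
        lambda x: abeles_reflectivity(slabs, x, roughness_model, dz=dz), q
    )
    return apply_scale_background(raw, scale, background)
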
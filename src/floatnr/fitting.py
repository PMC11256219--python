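"""Simultaneous fitting of bare-surface and membrane datasets across contrasts.

A :class:`FitProblem` couples several reflectivity datasets to one shared
:class:`~floatnr.model.Underlayers` and per-condition membrane models.
Parameter sharing is by object identity, so the under-layers are constrained
by every dataset at once — the bare-surface curves pin down the solid layers
while the membrane curves resolve the floating structure.  The objective is
the standard chi-squared,

    χ² = Σ_datasets Σ_i ((R_model(Q_i) − R_i) / dR_i)²,

with the model curve including resolution smearing and the per-dataset
scale/background nuisance terms.  Optimization is a differential-evolution
global stage followed by a bounded least-squares polish.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

from .materials import DEFAULT_MATERIALS, SolventContrast
from .model import (
    FloatingMembraneModel,
    Parameter,
    Underlayers,
    model_reflectivity,
)
from .kernel import QGrid

__all__ = ["ReflectivityDataset", "FitProblem", "fit_global", "fit_local"]


@dataclass(eq=False)
class ReflectivityDataset:
    """One measured (or simulated) reflectivity curve.

    Arrays ``q`` [Å⁻¹], ``r``, ``dr`` (1σ uncertainties, required by the
    likelihood) and optional ``dq`` (FWHM resolution per point).  Tagged
    with its solvent contrast, sample phase ("bare" before membrane
    deposition, "membrane" after) and a free-form condition label such as
    "Ca", "Ca+Na" or "EDTA".
    """

    q: np.ndarray
    r: np.ndarray
    dr: np.ndarray
    contrast: SolventContrast = None
    phase: str = "membrane"
    condition: str = ""
    dq: np.ndarray | None = None
    name: str = ""

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        self.dr = np.asarray(self.dr, dtype=float)
        if not (self.q.shape == self.r.shape == self.dr.shape):
            raise ValueError("q, r, dr must have equal lengths")
        if self.dq is not None:
            self.dq = np.asarray(self.dq, dtype=float)
            if self.dq.shape != self.q.shape:
                raise ValueError("dq must match q in length")
        if np.any(self.dr <= 0):
            raise ValueError("dr must be strictly positive everywhere")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be sorted strictly ascending")
        if self.phase not in ("bare", "membrane"):
            raise ValueError(f"phase must be 'bare' or 'membrane', got {self.phase!r}")
        if not self.name:
            label = self.condition or self.phase
            cname = self.contrast.name if self.contrast is not None else "?"
            self.name = f"{label}:{cname}"

    def __len__(self):
        return self.q.size

    def dq_over_q(self, default: float = 0.035) -> float:
        if self.dq is not None:
            return float(np.median(self.dq / self.q))
        return default


@dataclass(eq=False)
class _Entry:
    dataset: ReflectivityDataset
    membrane: FloatingMembraneModel | None
    scale: Parameter
    background: Parameter


class FitProblem:
    """Datasets + shared under-layers + per-condition membranes + nuisances."""

    def __init__(
        self,
        underlayers: Underlayers,
        datasets: Sequence[ReflectivityDataset],
        membranes: Mapping[str, FloatingMembraneModel]
        | FloatingMembraneModel
        | None = None,
        materials=DEFAULT_MATERIALS,
        roughness_model: str = "auto",
        dz: float = 1.0,
        fit_scale: bool = False,
        fit_background: bool = False,
        scale_bounds: tuple[float, float] = (0.8, 1.2),
        background_bounds: tuple[float, float] = (0.0, 1e-4),
        default_dq_over_q: float = 0.035,
    ):
        self.underlayers = underlayers
        self.materials = materials
        self.roughness_model = roughness_model
        self.dz = dz
        self.default_dq_over_q = default_dq_over_q
        if not any(ds.phase == "bare" for ds in datasets):
            warnings.warn(
                "no bare-surface datasets in the problem: under-layer "
                "parameters are constrained only through the membrane "
                "curves and may not be identifiable",
                stacklevel=2,
            )
        self.entries: list[_Entry] = []
        for ds in datasets:
            if ds.phase == "bare":
                mem = None
            elif isinstance(membranes, FloatingMembraneModel) or membranes is None:
                mem = membranes
                if mem is None:
                    raise ValueError(
                        f"dataset {ds.name} is a membrane measurement but no "
                        "membrane model was given"
                    )
            else:
                try:
                    mem = membranes[ds.condition]
                except KeyError:
                    raise KeyError(
                        f"no membrane model for condition {ds.condition!r}"
                    ) from None
            scale = Parameter(
                f"scale[{ds.name}]", 1.0, bounds=scale_bounds, vary=fit_scale
            )
            background = Parameter(
                f"background[{ds.name}]", 1e-6, bounds=background_bounds,
                vary=fit_background,
            )
            self.entries.append(_Entry(ds, mem, scale, background))

    # -- parameter bookkeeping -------------------------------------------
    def parameters(self) -> list[Parameter]:
        seen, out = set(), []
        groups = [self.underlayers.parameters()]
        for e in self.entries:
            if e.membrane is not None:
                groups.append(e.membrane.parameters())
        for e in self.entries:
            groups.append([e.scale, e.background])
        for group in groups:
            for p in group:
                if id(p) not in seen:
                    seen.add(id(p))
                    out.append(p)
        return out

    def varying_parameters(self) -> list[Parameter]:
        return [p for p in self.parameters() if p.vary]

    def varying_values(self) -> np.ndarray:
        return np.array([p.value for p in self.varying_parameters()])

    def set_varying_values(self, x: Sequence[float]) -> None:
        params = self.varying_parameters()
        if len(x) != len(params):
            raise ValueError(
                f"expected {len(params)} values, got {len(x)}"
            )
        for p, v in zip(params, x):
            p.value = v

    def varying_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        params = self.varying_parameters()
        lo = np.array([p.bounds[0] for p in params])
        hi = np.array([p.bounds[1] for p in params])
        if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi))):
            bad = [p.name for p in params if not np.all(np.isfinite(p.bounds))]
            raise ValueError(f"varying parameters must be bounded: {bad}")
        return lo, hi

    def find_parameter(self, name: str) -> Parameter:
        for p in self.parameters():
            if p.name == name:
                return p
        raise KeyError(f"no parameter named {name!r}")

    # -- model evaluation -------------------------------------------------
    def model_for(self, entry: _Entry) -> np.ndarray:
        ds = entry.dataset
        grid = QGrid(ds.q, ds.dq_over_q(self.default_dq_over_q))
        return model_reflectivity(
            self.underlayers,
            entry.membrane,
            ds.contrast,
            grid,
            scale=entry.scale.value,
            background=entry.background.value,
            materials=self.materials,
            roughness_model=self.roughness_model,
            dz=self.dz,
        )

    def residuals(self) -> np.ndarray:
        return np.concatenate(
            [
                (self.model_for(e) - e.dataset.r) / e.dataset.dr
                for e in self.entries
            ]
        )

    def chi_squared(self) -> float:
        r = self.residuals()
        return float(r @ r)

    @property
    def n_points(self) -> int:
        return sum(len(e.dataset) for e in self.entries)


def fit_global(
    problem: FitProblem,
    seed: int,
    popsize: int = 15,
    maxiter: int = 60,
    tol: float = 0.005,
    init: str = "latinhypercube",
) -> optimize.OptimizeResult:
    """Differential-evolution global search within bounds, then set best.

    The population-based stage stands in for the genetic step of the
    original analysis; it is deterministic for a given seed.
    """
    params = problem.varying_parameters()
    if not params:
        return optimize.OptimizeResult(
            x=np.empty(0), fun=problem.chi_squared(), success=True, nfev=0
        )
    lo, hi = problem.varying_bounds()

    def objective(x):
        problem.set_varying_values(x)
        try:
            return problem.chi_squared()
        except ValueError:
            # infeasible composition (occupancy > 100%): hard penalty wall
            return 1e30

    result = optimize.differential_evolution(
        objective,
        bounds=list(zip(lo, hi)),
        seed=seed,
        popsize=popsize,
        maxiter=maxiter,
        tol=tol,
        init=init,
        polish=False,
        updating="immediate",
    )
    problem.set_varying_values(result.x)
    return result


def fit_local(
    problem: FitProblem, start: Sequence[float] | None = None
) -> optimize.OptimizeResult:
    """Bounded least-squares polish from ``start`` (default: current values).

    Guaranteed not to increase χ² relative to the starting point.
    """
    params = problem.varying_parameters()
    if not params:
        return optimize.OptimizeResult(
            x=np.empty(0), cost=0.5 * problem.chi_squared(), success=True
        )
    lo, hi = problem.varying_bounds()
    x0 = problem.varying_values() if start is None else np.asarray(start, float)
    if np.any(x0 < lo) or np.any(x0 > hi):
        raise ValueError("start point outside parameter bounds")

    n_res = problem.n_points

    def residuals(x):
        problem.set_varying_values(x)
        try:
            return problem.residuals()
        except ValueError:
            # infeasible composition: flat penalty wall the trust region
            # backs away from
            return np.full(n_res, 1e8)

    result = optimize.least_squares(
        residuals, x0, bounds=(lo, hi), method="trf",
        x_scale=np.maximum(hi - lo, 1e-12) / 10.0,
        diff_step=1e-4,
    )
    problem.set_varying_values(result.x)
    return result
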
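"""Readers, writers, config handling and pipeline orchestration.

Reflectivity files are plain ASCII: '#' comment lines, then whitespace- or
comma-delimited columns Q [Å⁻¹], R, dR [, dQ FWHM].  Units follow the
package-wide conventions (lengths in Å, Q in Å⁻¹, SLD in 1e-6 Å⁻²) and are
stated in every header.  The run configuration is a single YAML file
declaring materials, contrasts, the layer model with per-parameter
value/bounds/vary flags, the dataset manifest and fit settings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .fitting import FitProblem, ReflectivityDataset, fit_global, fit_local
from .materials import (
    DEFAULT_MATERIALS,
    NAMED_CONTRASTS,
    Material,
    SolventContrast,
)
from .model import FloatingMembraneModel, Parameter, Underlayers, component_profile
from .simulate import INTER, SURF, InstrumentSpec, simulate_dataset
from .uncertainty import posterior_bands, run_dram

__all__ = [
    "read_reflectivity",
    "write_reflectivity",
    "write_ort",
    "load_config",
    "run_pipeline",
]


def read_reflectivity(
    path,
    contrast: SolventContrast | str | None = None,
    phase: str | None = None,
    condition: str = "",
) -> ReflectivityDataset:
    """Parse an ASCII reflectivity file into a dataset.

    Metadata absent from the arguments is taken from ``# key: value``
    comment lines (keys: contrast, phase, condition) when present.
    Rows with descending Q are sorted ascending with a warning; malformed
    rows and non-positive dR raise errors naming the line.
    """
    path = Path(path)
    meta = {}
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    meta[key.strip().lower()] = val.strip()
                continue
            fields = line.replace(",", " ").split()
            if len(fields) not in (3, 4):
                raise ValueError(
                    f"{path.name}:{lineno}: expected 3 or 4 columns, "
                    f"got {len(fields)}"
                )
            try:
                values = [float(f) for f in fields]
            except ValueError:
                raise ValueError(
                    f"{path.name}:{lineno}: non-numeric field in {line!r}"
                ) from None
            if values[2] <= 0:
                raise ValueError(
                    f"{path.name}:{lineno}: dR must be > 0, got {values[2]}"
                )
            rows.append(values)
    if not rows:
        raise ValueError(f"{path.name}: no data rows")
    ncol = max(len(r) for r in rows)
    data = np.array([r + [np.nan] * (ncol - len(r)) for r in rows])
    order = np.argsort(data[:, 0])
    if not np.all(order == np.arange(len(order))):
        warnings.warn(f"{path.name}: Q not ascending; sorting", stacklevel=2)
        data = data[order]
    if contrast is None and "contrast" in meta:
        contrast = meta["contrast"]
    if isinstance(contrast, str):
        contrast = NAMED_CONTRASTS[contrast]
    phase = phase or meta.get("phase", "membrane")
    condition = condition or meta.get("condition", "")
    dq = data[:, 3] if ncol == 4 and not np.any(np.isnan(data[:, 3])) else None
    return ReflectivityDataset(
        q=data[:, 0], r=data[:, 1], dr=data[:, 2], dq=dq,
        contrast=contrast, phase=phase, condition=condition,
    )


def write_reflectivity(ds: ReflectivityDataset, path, extra_header: str = "") -> None:
    """Write a dataset in the same ASCII format the reader consumes."""
    cols = [ds.q, ds.r, ds.dr]
    names = "Q[1/Angstrom] R dR"
    if ds.dq is not None:
        cols.append(ds.dq)
        names += " dQ_FWHM[1/Angstrom]"
    header = [
        "reflectivity dataset",
        f"contrast: {ds.contrast.name if ds.contrast else ''}",
        f"phase: {ds.phase}",
    ]
    if ds.condition:
        header.append(f"condition: {ds.condition}")
    if extra_header:
        header.extend(extra_header.splitlines())
    header.append(f"columns: {names}")
    np.savetxt(path, np.column_stack(cols), header="\n".join(header), fmt="%.8e")


def write_ort(ds: ReflectivityDataset, path) -> None:
    """Minimal ORSO .ort-style export (self-written text header + columns)."""
    lines = [
        "# # ORSO reflectivity data file | 1.0 standard | YAML encoding | https://www.reflectometry.org/",
        "# data_source:",
        "#   measurement:",
        f"#     instrument_settings: {{incident_angle: null, wavelength: null}}",
        "# columns:",
        "# - {name: Qz, unit: 1/angstrom}",
        "# - {name: R}",
        "# - {name: sR}",
        "# - {name: sQz, unit: 1/angstrom}",
    ]
    dq = ds.dq if ds.dq is not None else np.zeros_like(ds.q)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        for row in zip(ds.q, ds.r, ds.dr, dq):
            fh.write(" ".join(f"{v:.8e}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# configuration


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    cfg.setdefault("_config_dir", str(Path(path).resolve().parent))
    cfg.setdefault(
        "_config_hash",
        hashlib.sha256(
            json.dumps(
                {k: v for k, v in cfg.items() if not k.startswith("_")},
                sort_keys=True, default=str,
            ).encode()
        ).hexdigest()[:16],
    )
    return cfg


def _param_from_spec(name, spec, default_bounds=None):
    if isinstance(spec, dict):
        return Parameter(
            name,
            spec["value"],
            bounds=spec.get("bounds", default_bounds),
            vary=spec.get("vary", False),
            shared_group=spec.get("shared_group"),
        )
    return Parameter(name, float(spec), bounds=default_bounds)


def _apply_block(obj, block: dict):
    for key, spec in (block or {}).items():
        if not hasattr(obj, key):
            raise KeyError(f"unknown model field {key!r}")
        current = getattr(obj, key)
        if isinstance(current, Parameter):
            p = _param_from_spec(key, spec, default_bounds=current.bounds)
            setattr(obj, key, p)
        else:
            setattr(obj, key, spec)
    return obj


def _build_materials(cfg):
    mats = dict(DEFAULT_MATERIALS)
    for name, spec in (cfg.get("materials") or {}).items():
        mats[name] = Material(
            name, spec["sld_h2o"], spec.get("sld_d2o")
        )
    return mats


def _build_contrast(name, cfg):
    custom = cfg.get("contrasts") or {}
    if name in custom:
        return SolventContrast(name, float(custom[name]))
    return NAMED_CONTRASTS[name]


def _build_instrument(cfg):
    spec = cfg.get("instrument", "INTER")
    if isinstance(spec, str):
        return {"INTER": INTER, "SURF": SURF}[spec]
    return InstrumentSpec(**spec)


def _build_models(cfg):
    under = Underlayers()
    _apply_block(under, cfg.get("underlayers"))
    membranes = {}
    for cond, block in (cfg.get("membranes") or {}).items():
        m = FloatingMembraneModel()
        _apply_block(m, block)
        membranes[cond] = m
    return under, membranes


def _collect_datasets(cfg, under, membranes, materials, seed):
    instrument = _build_instrument(cfg)
    datasets = []
    sim = cfg.get("simulate")
    if sim:
        specs = sim["datasets"]
        seeds = np.random.SeedSequence(seed).generate_state(len(specs))
        for k, spec in enumerate(specs):
            contrast = _build_contrast(spec["contrast"], cfg)
            membrane = (
                None if spec.get("phase", "membrane") == "bare"
                else membranes[spec.get("condition") or next(iter(membranes))]
            )
            datasets.append(
                simulate_dataset(
                    under, membrane, instrument, contrast, int(seeds[k]),
                    condition=spec.get("condition", ""),
                    counting_time=sim.get("counting_time", 1.0),
                    materials=materials,
                    roughness_model=cfg.get("roughness_model", "auto"),
                )
            )
    else:
        base = Path(cfg.get("_config_dir", "."))
        for spec in cfg.get("datasets", []):
            p = Path(spec["path"])
            if not p.is_absolute():
                p = base / p
            if not p.exists():
                raise FileNotFoundError(f"dataset file not found: {p}")
            datasets.append(
                read_reflectivity(
                    p,
                    contrast=_build_contrast(spec["contrast"], cfg),
                    phase=spec.get("phase"),
                    condition=spec.get("condition", ""),
                )
            )
    if not datasets:
        raise ValueError("config declares no datasets")
    return datasets


def run_pipeline(cfg: dict, output_dir=None) -> dict:
    """Execute simulate (optional) → fit → DRAM → bands → profile export.

    Every stochastic stage derives its seed from the mandatory top-level
    ``seed``; outputs carry the config hash and seed so reruns are
    reproducible.  Returns the in-memory results bundle.
    """
    if "seed" not in cfg:
        raise ValueError("config must set an integer 'seed'")
    seed = int(cfg["seed"])
    out = Path(output_dir or cfg.get("output_dir", "results"))
    out.mkdir(parents=True, exist_ok=True)
    materials = _build_materials(cfg)
    under, membranes = _build_models(cfg)
    datasets = _collect_datasets(cfg, under, membranes, materials, seed)

    fit_cfg = cfg.get("fit") or {}
    problem = FitProblem(
        under, datasets, membranes=membranes or None,
        materials=materials,
        roughness_model=cfg.get("roughness_model", "auto"),
        fit_scale=fit_cfg.get("fit_scale", False),
        fit_background=fit_cfg.get("fit_background", False),
    )
    stamp = (
        f"config_hash: {cfg.get('_config_hash', '?')}\n"
        f"seed: {seed}\nfloatnr_version: {__version__}"
    )
    opt = fit_cfg.get("optimizer") or {}
    result_global = fit_global(
        problem, seed=seed,
        popsize=opt.get("popsize", 15),
        maxiter=opt.get("maxiter", 40),
        tol=opt.get("tol", 0.005),
    )
    result_local = fit_local(problem)
    mcmc = fit_cfg.get("mcmc") or {}
    posterior = run_dram(
        problem,
        n_steps=mcmc.get("steps", 2000),
        seed=seed + 1,
        burn_fraction=mcmc.get("burn_fraction", 0.25),
    )
    bands = posterior_bands(
        posterior, problem,
        n_draws=(fit_cfg.get("bands") or {}).get("draws", 200),
        seed=seed + 2,
    )

    (out / "parameters.tsv").write_text(
        f"# {stamp.replace(chr(10), '; ')}\n" + posterior.summary_table() + "\n"
    )
    posterior.to_text(out / "chains.tsv")
    for e in problem.entries:
        band = bands["reflectivity"][e.dataset.name]
        arr = np.column_stack(
            [e.dataset.q, e.dataset.r, e.dataset.dr,
             band["mean"], band["lo"], band["hi"]]
        )
        np.savetxt(
            out / f"reflectivity_{e.dataset.name.replace(':', '_')}.tsv",
            arr,
            header=f"{stamp}\nQ[1/Angstrom] R dR model_mean model_lo model_hi",
            delimiter="\t", fmt="%.8e",
        )
    for cond, mem in (membranes or {}).items():
        prof = component_profile(under, mem)
        prof.to_tsv(out / f"profile_{cond}.tsv")
    log = [
        stamp,
        f"datasets: {[e.dataset.name for e in problem.entries]}",
        f"n_points: {problem.n_points}",
        f"chi2_global: {result_global.fun if result_global.x.size else problem.chi_squared():.6g}",
        f"chi2_final: {problem.chi_squared():.6g}",
        f"dram_acceptance: {posterior.acceptance_rate:.3f}",
    ]
    (out / "log.txt").write_text("\n".join(log) + "\n")
    return {
        "problem": problem,
        "posterior": posterior,
        "bands": bands,
        "global": result_global,
        "local": result_local,
        "output_dir": out,
    }
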
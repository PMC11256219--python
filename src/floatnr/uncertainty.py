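"""Bayesian uncertainty quantification by Delayed-Rejection Adaptive Metropolis.

The posterior is exp(−χ²/2) with independent uniform priors over the
parameter bounds.  The sampler is the DRAM variant of random-walk
Metropolis: a second, down-scaled proposal is attempted after each
rejection (delayed rejection), and the proposal covariance is adapted
periodically to the sample covariance of the chain so far (adaptive
Metropolis).  Parameter uncertainties are summarized as shortest 65%
percentile intervals of the marginal posteriors, and curve/profile
uncertainties as pointwise shortest intervals over curves recomputed from
resampled chain draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .model import component_profile, sld_profile

__all__ = [
    "Posterior",
    "shortest_interval",
    "dram_sample",
    "run_dram",
    "posterior_bands",
]


def shortest_interval(samples: Sequence[float], level: float = 0.65):
    """Narrowest contiguous window of sorted samples holding ``level`` mass.

    Returns ``(lo, hi)``; ties broken toward the leftmost window.  Requires
    at least 50 samples for a meaningful interval.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    s = np.sort(np.asarray(samples, dtype=float).ravel())
    n = s.size
    if n < 50:
        raise ValueError(f"need at least 50 samples, got {n}")
    m = max(2, int(math.ceil(level * n)))
    widths = s[m - 1:] - s[: n - m + 1]
    i = int(np.argmin(widths))
    return float(s[i]), float(s[i + m - 1])


@dataclass
class Posterior:
    """MCMC output: full chain, burn-in marker, and interval summaries."""

    chain: np.ndarray  # (n_steps, n_params), includes burn-in
    log_post: np.ndarray
    param_names: list[str]
    bounds: np.ndarray  # (n_params, 2)
    burn_in: int
    acceptance_rate: float

    @property
    def samples(self) -> np.ndarray:
        return self.chain[self.burn_in:]

    def means(self) -> np.ndarray:
        return self.samples.mean(axis=0)

    def intervals(self, level: float = 0.65) -> dict[str, tuple[float, float]]:
        out = {}
        for j, name in enumerate(self.param_names):
            col = self.samples[:, j]
            if np.ptp(col) == 0.0:
                out[name] = (float(col[0]), float(col[0]))
            else:
                out[name] = shortest_interval(col, level)
        return out

    def summary_table(self, level: float = 0.65) -> str:
        """Tab-separated summary: parameter, mean, interval lo, interval hi."""
        lines = ["parameter\tmean\tlo\thi"]
        iv = self.intervals(level)
        for name, mean in zip(self.param_names, self.means()):
            lo, hi = iv[name]
            lines.append(f"{name}\t{mean:.6g}\t{lo:.6g}\t{hi:.6g}")
        return "\n".join(lines)

    def to_text(self, path) -> None:
        header = "DRAM chain samples (including burn-in of %d)\n%s" % (
            self.burn_in,
            "\t".join(self.param_names),
        )
        np.savetxt(path, self.chain, header=header, delimiter="\t", fmt="%.8g")


def dram_sample(
    log_post: Callable[[np.ndarray], float],
    start: np.ndarray,
    bounds: np.ndarray,
    n_steps: int,
    seed: int,
    cov0: np.ndarray | None = None,
    adapt_interval: int = 100,
    adapt_start: int = 200,
    dr_scale: float = 5.0,
    burn_fraction: float = 0.25,
    param_names: Sequence[str] | None = None,
) -> Posterior:
    """Core DRAM sampler over an arbitrary log-posterior with box bounds.

    ``cov0`` is the initial proposal covariance (default: diagonal with
    standard deviations of 1% of each bound width).  The first-stage
    proposal is N(x, C); on rejection a second-stage proposal N(x, C/s²)
    with s = ``dr_scale`` is attempted with the delayed-rejection
    acceptance ratio.  From ``adapt_start`` on, C is refreshed every
    ``adapt_interval`` steps as (2.38²/d)·cov(chain) + εI.  Deterministic
    for a given seed.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(start, dtype=float).copy()
    bounds = np.asarray(bounds, dtype=float)
    d = x.size
    if bounds.shape != (d, 2):
        raise ValueError("bounds must have shape (n_params, 2)")
    if np.any(x < bounds[:, 0]) or np.any(x > bounds[:, 1]):
        raise ValueError("start point outside bounds")
    if n_steps < 8:
        raise ValueError("n_steps too small to produce a usable chain")
    widths = bounds[:, 1] - bounds[:, 0]
    if cov0 is None:
        cov0 = np.diag((0.01 * np.maximum(widths, 1e-12)) ** 2)
    C = np.array(cov0, dtype=float)
    L = np.linalg.cholesky(C)
    sd = 2.38**2 / d
    eps = 1e-12 * np.maximum(widths, 1e-12) ** 2

    def in_bounds(y):
        return np.all(y >= bounds[:, 0]) and np.all(y <= bounds[:, 1])

    def lp(y):
        return log_post(y) if in_bounds(y) else -np.inf

    lp_x = lp(x)
    if not np.isfinite(lp_x):
        raise ValueError("log posterior not finite at the start point")
    chain = np.empty((n_steps, d))
    lps = np.empty(n_steps)
    Cinv = np.linalg.inv(C)
    accepted = 0
    for step in range(n_steps):
        z = rng.standard_normal(d)
        y1 = x + L @ z
        lp1 = lp(y1)
        log_a1 = lp1 - lp_x
        if np.log(rng.uniform()) < log_a1:
            x, lp_x = y1, lp1
            accepted += 1
        else:
            # delayed-rejection second stage with a down-scaled proposal
            y2 = x + (L / dr_scale) @ rng.standard_normal(d)
            lp2 = lp(y2)
            if np.isfinite(lp2):
                a1_y2y1 = min(1.0, np.exp(min(lp1 - lp2, 0.0)))
                a1_xy1 = min(1.0, np.exp(min(log_a1, 700.0)))
                dy2 = y1 - y2
                dx = y1 - x
                log_q_ratio = -0.5 * (dy2 @ Cinv @ dy2 - dx @ Cinv @ dx)
                num = (1.0 - a1_y2y1)
                den = (1.0 - a1_xy1)
                if den > 0 and num > 0:
                    log_a2 = lp2 - lp_x + log_q_ratio + np.log(num) - np.log(den)
                    if np.log(rng.uniform()) < log_a2:
                        x, lp_x = y2, lp2
                        accepted += 1
        chain[step] = x
        lps[step] = lp_x
        if step + 1 >= adapt_start and (step + 1) % adapt_interval == 0:
            hist = chain[: step + 1]
            Cnew = sd * np.cov(hist, rowvar=False).reshape(d, d) + sd * np.diag(eps)
            try:
                Lnew = np.linalg.cholesky(Cnew)
            except np.linalg.LinAlgError:
                continue
            C, L = Cnew, Lnew
            Cinv = np.linalg.inv(C)

    rate = accepted / n_steps
    if rate == 0.0:
        raise RuntimeError(
            "DRAM accepted no proposals: the starting covariance is likely "
            "far too wide or the start point sits on a likelihood cliff; "
            "provide a cov0 from a local fit, or start from the best fit"
        )
    names = (
        list(param_names)
        if param_names is not None
        else [f"p{j}" for j in range(d)]
    )
    return Posterior(
        chain=chain,
        log_post=lps,
        param_names=names,
        bounds=bounds,
        burn_in=int(burn_fraction * n_steps),
        acceptance_rate=rate,
    )


def _jacobian_covariance(problem, x, rel_step=1e-4):
    """Gaussian-approximation covariance (JᵀJ)⁻¹ of the weighted residuals."""
    lo, hi = problem.varying_bounds()
    r0 = None
    cols = []
    problem.set_varying_values(x)
    r0 = problem.residuals()
    for j in range(x.size):
        h = rel_step * max(abs(x[j]), 1e-3 * (hi[j] - lo[j]))
        xp = x.copy()
        xp[j] = min(x[j] + h, hi[j])
        if xp[j] == x[j]:
            xp[j] = max(x[j] - h, lo[j])
        problem.set_varying_values(xp)
        cols.append((problem.residuals() - r0) / (xp[j] - x[j]))
    problem.set_varying_values(x)
    J = np.column_stack(cols)
    try:
        return np.linalg.inv(J.T @ J)
    except np.linalg.LinAlgError:
        return None


def run_dram(
    problem,
    start: np.ndarray | None = None,
    n_steps: int = 5000,
    seed: int = 0,
    cov0: np.ndarray | None = None,
    **kwargs,
) -> Posterior:
    """DRAM sampling of a :class:`~floatnr.fitting.FitProblem` posterior.

    The likelihood is exp(−χ²/2); priors are uniform over bounds.  By
    default the initial proposal covariance is the Gaussian approximation
    (JᵀJ)⁻¹ at the start point (typically the best fit), which gives the
    adaptation a sensible starting scale.
    """
    params = problem.varying_parameters()
    if not params:
        raise ValueError("no varying parameters to sample")
    x0 = problem.varying_values() if start is None else np.asarray(start, float)
    problem.set_varying_values(x0)
    lo, hi = problem.varying_bounds()
    if cov0 is None:
        cov0 = _jacobian_covariance(problem, x0)
        if cov0 is not None:
            # keep proposal scales from exceeding the prior box
            sig = np.sqrt(np.diag(cov0))
            cap = (hi - lo) / 4.0
            inflate = np.minimum(cap / np.maximum(sig, 1e-300), 1.0)
            cov0 = cov0 * np.outer(inflate, inflate)
            cov0 = (2.38**2 / x0.size) * cov0
            try:
                np.linalg.cholesky(cov0)
            except np.linalg.LinAlgError:
                cov0 = None

    def log_post(x):
        problem.set_varying_values(x)
        try:
            return -0.5 * problem.chi_squared()
        except ValueError:
            # infeasible composition: zero posterior mass
            return -np.inf

    post = dram_sample(
        log_post,
        x0,
        np.column_stack([lo, hi]),
        n_steps,
        seed,
        cov0=cov0,
        param_names=[p.name for p in params],
        **kwargs,
    )
    problem.set_varying_values(x0)
    return post


def posterior_bands(
    posterior: Posterior,
    problem,
    n_draws: int = 1000,
    seed: int = 0,
    level: float = 0.65,
    include_profiles: bool = True,
    dz: float = 1.0,
):
    """Pointwise uncertainty envelopes from resampled posterior draws.

    Draws ``n_draws`` parameter vectors (with replacement) from the
    post-burn-in chain, recomputes every dataset's reflectivity — and, when
    ``include_profiles``, the SLD and component volume-fraction profiles per
    condition — and reports the pointwise mean ("best fit") together with
    shortest-``level`` envelopes.
    """
    samples = posterior.samples
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, samples.shape[0], size=n_draws)
    saved = problem.varying_values()

    # fixed profile grid wide enough for every draw
    z_grids = {}
    if include_profiles:
        for e in problem.entries:
            cond = e.dataset.condition or e.dataset.phase
            if cond not in z_grids:
                prof = component_profile(problem.underlayers, e.membrane, dz=dz)
                span = prof.z[-1] - prof.z[0]
                extra = 0.5 * span + 100.0
                n = int(np.ceil((span + extra) / dz))
                z_grids[cond] = (
                    prof.z[0] + dz * np.arange(n),
                    e.membrane,
                )

    refl = {e.dataset.name: [] for e in problem.entries}
    slds = {}
    vfs = {}
    for i in idx:
        problem.set_varying_values(samples[i])
        for e in problem.entries:
            refl[e.dataset.name].append(problem.model_for(e))
        if include_profiles:
            for cond, (z, mem) in z_grids.items():
                contrast = next(
                    e.dataset.contrast
                    for e in problem.entries
                    if (e.dataset.condition or e.dataset.phase) == cond
                )
                _, rho = sld_profile(
                    problem.underlayers, mem, contrast,
                    materials=problem.materials, z=z,
                )
                slds.setdefault(cond, []).append(rho)
                g = component_profile(
                    problem.underlayers, mem, z=z
                ).grouped()
                vfs.setdefault(cond, {})
                for comp, arr in g.items():
                    vfs[cond].setdefault(comp, []).append(arr)
    problem.set_varying_values(saved)

    def envelope(stack):
        arr = np.asarray(stack)
        mean = arr.mean(axis=0)
        if arr.shape[0] < 50 or np.allclose(arr, arr[0]):
            return mean, arr.min(axis=0), arr.max(axis=0)
        lo = np.empty(arr.shape[1])
        hi = np.empty(arr.shape[1])
        for j in range(arr.shape[1]):
            col = arr[:, j]
            if np.ptp(col) == 0.0:
                lo[j] = hi[j] = col[0]
            else:
                lo[j], hi[j] = shortest_interval(col, level)
        return mean, lo, hi

    out = {"reflectivity": {}, "sld": {}, "volume_fraction": {}}
    for e in problem.entries:
        mean, lo, hi = envelope(refl[e.dataset.name])
        out["reflectivity"][e.dataset.name] = {
            "q": e.dataset.q, "mean": mean, "lo": lo, "hi": hi,
        }
    for cond in slds:
        mean, lo, hi = envelope(slds[cond])
        out["sld"][cond] = {
            "z": z_grids[cond][0], "mean": mean, "lo": lo, "hi": hi,
        }
    for cond, comps in vfs.items():
        out["volume_fraction"][cond] = {"z": z_grids[cond][0]}
        for comp, stack in comps.items():
            mean, lo, hi = envelope(stack)
            out["volume_fraction"][cond][comp] = {
                "mean": mean, "lo": lo, "hi": hi,
            }
    return out
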
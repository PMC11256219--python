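"""Specular reflectivity of a slab stack via the Abelès optical matrix method.

The stack is ordered fronting → backing.  The beam enters through the
silicon substrate (inverted solid–liquid geometry), so the fronting medium
is silicon and the backing medium is the bulk solvent; the z axis is zero at
the silicon surface and increases toward solution.  Each slab's ``roughness``
is the Gaussian width σ of its *top* (solution-side) interface.

Two roughness treatments are provided:

``nevot_croce``
    Gaussian damping of the interfacial Fresnel coefficients.  Fast, but an
    approximation that degrades once σ becomes comparable to the adjacent
    layer thicknesses.
``microslice``
    The erf-broadened SLD profile is discretized into thin (default 1 Å)
    zero-roughness sub-slabs before the matrix recursion.  This is the
    reference treatment and remains valid at arbitrary σ/d.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.special import erf

__all__ = [
    "Slab",
    "QGrid",
    "qz_from_angle",
    "abeles_reflectivity",
    "microslice_profile",
    "smear_gaussian",
    "apply_scale_background",
]

# FWHM of a unit-σ Gaussian
_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class Slab:
    """One homogeneous layer: thickness [Å], SLD [1e-6 Å⁻²], top roughness [Å].

    Fronting and backing slabs are semi-infinite; their thickness is ignored
    by the recursion (conventionally set to 0).
    """

    thickness: float
    sld: float
    roughness: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.thickness < 0:
            raise ValueError(f"slab thickness must be >= 0, got {self.thickness}")
        if self.roughness < 0:
            raise ValueError(f"slab roughness must be >= 0, got {self.roughness}")


@dataclass(frozen=True)
class QGrid:
    """Momentum-transfer grid [Å⁻¹] with fractional FWHM resolution dQ/Q."""

    q_values: np.ndarray
    dq_over_q: float = 0.0

    def __post_init__(self) -> None:
        q = np.asarray(self.q_values, dtype=float)
        object.__setattr__(self, "q_values", q)
        if q.ndim != 1 or q.size == 0:
            raise ValueError("q_values must be a non-empty 1-d array")
        if np.any(q <= 0):
            raise ValueError("q_values must be positive")
        if np.any(np.diff(q) <= 0):
            raise ValueError("q_values must be strictly increasing")
        if self.dq_over_q < 0:
            raise ValueError("dq_over_q must be >= 0")


def qz_from_angle(theta: float, wavelength: float) -> float:
    """Momentum transfer Q_z = 4π sin(θ)/λ for glancing angle θ [deg], λ [Å]."""
    if wavelength <= 0:
        raise ValueError(f"wavelength must be > 0, got {wavelength}")
    if not 0 <= theta < 90:
        raise ValueError(f"glancing angle must be in [0, 90), got {theta}")
    return 4.0 * np.pi * np.sin(np.radians(theta)) / wavelength


def _stack_arrays(slabs: Sequence[Slab]):
    d = np.array([s.thickness for s in slabs], dtype=float)
    rho = np.array([s.sld for s in slabs], dtype=float)
    # roughness of interface i (between slab i and slab i+1) lives on slab i
    sigma = np.array([s.roughness for s in slabs[:-1]], dtype=float)
    return d, rho, sigma


def sliced_stack_arrays(fronting_sld: float, profile: np.ndarray,
                        backing_sld: float, dz: float):
    """Layer arrays for a stack of ``dz``-thick sub-slabs with given SLDs.

    Each sub-slab interface carries the negative squared width −dz²/12 that
    deconvolves the box smoothing introduced by midpoint discretization of a
    continuous profile (accurate for profiles smooth on the dz scale).
    """
    n = profile.size
    d = np.concatenate([[0.0], np.full(n, dz), [0.0]])
    rho = np.concatenate([[fronting_sld], profile, [backing_sld]])
    sigma_sq = np.full(n + 1, -dz * dz / 12.0)
    return d, rho, sigma_sq


def _abeles_numpy(q: np.ndarray, d: np.ndarray, rho: np.ndarray,
                  sigma_sq: np.ndarray) -> np.ndarray:
    """Matrix recursion for |r|² on arrays of layers.

    ``d``, ``rho`` have length n_layers (fronting first); ``sigma_sq`` has
    length n_layers-1 and is the *squared* Gaussian width of each interface,
    applied as a Névot–Croce factor exp(−2·k_a·k_b·σ²) on the Fresnel
    coefficient.  Negative σ² is allowed (used by the microslice mode to
    deconvolve the discretization box).
    """
    q = np.asarray(q, dtype=float).ravel()
    nlay = len(d)
    # wavevector normal component in each layer, relative to fronting
    k0sq = (q / 2.0) ** 2
    # SLDs are in 1e-6 Å^-2
    kn = np.sqrt(
        k0sq[:, None].astype(complex)
        - 4.0e-6 * np.pi * (rho[None, :] - rho[0])
    )  # (nq, nlay)

    # interfacial Fresnel coefficients with Névot-Croce factor
    ka, kb = kn[:, :-1], kn[:, 1:]
    rj = (ka - kb) / (ka + kb) * np.exp(-2.0 * ka * kb * sigma_sq[None, :])

    # phase accumulated in each internal layer above its lower interface
    beta = np.ones_like(rj)
    if nlay > 2:
        beta[:, 1:] = np.exp(1j * kb[:, :-1] * d[None, 1:-1])

    m00 = beta[:, 0]
    m01 = rj[:, 0] * beta[:, 0]
    m10 = rj[:, 0] / beta[:, 0]
    m11 = 1.0 / beta[:, 0]
    for j in range(1, nlay - 1):
        e = beta[:, j]
        a10 = rj[:, j] / e
        a01 = rj[:, j] * e
        n00 = m00 * e + m01 * a10
        n01 = m00 * a01 + m01 / e
        n10 = m10 * e + m11 * a10
        n11 = m10 * a01 + m11 / e
        m00, m01, m10, m11 = n00, n01, n10, n11
    r = m10 / m00
    refl = np.abs(r) ** 2
    # numerical guard: non-absorbing total reflection can exceed 1 by eps
    return np.minimum(refl, 1.0)


try:  # pragma: no cover - exercised indirectly
    from numba import njit as _njit

    @_njit(cache=True, fastmath=False)
    def _abeles_jit(q, d, rho, sigma_sq):  # pragma: no cover
        nq = q.shape[0]
        nlay = d.shape[0]
        out = np.empty(nq)
        for iq in range(nq):
            k0sq = (q[iq] / 2.0) ** 2
            ka = np.sqrt(complex(k0sq, 0.0))
            m00 = complex(1.0, 0.0)
            m01 = complex(0.0, 0.0)
            m10 = complex(0.0, 0.0)
            m11 = complex(1.0, 0.0)
            for j in range(nlay - 1):
                kb = np.sqrt(
                    complex(k0sq - 4.0e-6 * np.pi * (rho[j + 1] - rho[0]), 0.0)
                )
                rj = (ka - kb) / (ka + kb) * np.exp(
                    -2.0 * ka * kb * sigma_sq[j]
                )
                if j == 0:
                    e = complex(1.0, 0.0)
                else:
                    e = np.exp(1j * ka * d[j])
                a01 = rj * e
                a10 = rj / e
                n00 = m00 * e + m01 * a10
                n01 = m00 * a01 + m01 / e
                n10 = m10 * e + m11 * a10
                n11 = m10 * a01 + m11 / e
                m00, m01, m10, m11 = n00, n01, n10, n11
                ka = kb
            r = m10 / m00
            refl = r.real * r.real + r.imag * r.imag
            out[iq] = refl if refl < 1.0 else 1.0
        return out

    def _abeles(q, d, rho, sigma_sq):
        q = np.ascontiguousarray(np.asarray(q, dtype=float).ravel())
        return _abeles_jit(
            q,
            np.ascontiguousarray(d, dtype=np.float64),
            np.ascontiguousarray(rho, dtype=np.float64),
            np.ascontiguousarray(sigma_sq, dtype=np.float64),
        )

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _abeles = _abeles_numpy
    HAVE_NUMBA = False


def microslice_profile(slabs: Sequence[Slab], dz: float = 1.0,
                       n_sigma: float = 4.5):
    """Discretize the erf-broadened SLD profile of a stack into sub-slabs.

    Returns ``(z_edges_midpoints, sld_values)`` on a grid of spacing ``dz``
    spanning all interfaces ± ``n_sigma`` × roughness (at least ``n_sigma`` Å).
    The profile is the analytic sum of erf steps:
    ρ(z) = ρ_0 + Σ_i (ρ_{i+1} − ρ_i) · ½(1 + erf((z − z_i)/(√2 σ_i))).
    """
    d, rho, sigma = _stack_arrays(slabs)
    z_if = np.concatenate([[0.0], np.cumsum(d[1:-1])])  # interface positions
    pad = n_sigma * np.maximum(sigma, 1.0)
    z_lo = z_if[0] - pad[0]
    z_hi = z_if[-1] + pad[-1]
    n = max(int(np.ceil((z_hi - z_lo) / dz)), 2)
    z = z_lo + dz * (np.arange(n) + 0.5)
    prof = np.full(n, rho[0])
    for zi, si, dr in zip(z_if, sigma, np.diff(rho)):
        if si > 0:
            prof += dr * 0.5 * (1.0 + erf((z - zi) / (np.sqrt(2.0) * si)))
        else:
            prof += dr * (z >= zi)
    return z, prof


def _microsliced_stack(slabs: Sequence[Slab], dz: float):
    _, prof = microslice_profile(slabs, dz=dz)
    return sliced_stack_arrays(slabs[0].sld, prof, slabs[-1].sld, dz)


def invalid_nc_interfaces(slabs: Sequence[Slab]) -> list[int]:
    """Interfaces where the Névot–Croce factor is unreliable.

    Interface ``j`` (between slab j and j+1) is flagged when its roughness
    is at least one third of an adjacent *finite* layer thickness.  Returns
    the flagged interface indices.
    """
    bad = []
    for j in range(len(slabs) - 1):
        sigma = slabs[j].roughness
        if sigma == 0:
            continue
        adjacent = []
        if 0 < j:  # slab j finite (not fronting)
            adjacent.append(slabs[j].thickness)
        if j + 1 < len(slabs) - 1:  # slab j+1 finite (not backing)
            adjacent.append(slabs[j + 1].thickness)
        if adjacent and sigma >= min(adjacent) / 3.0:
            bad.append(j)
    return bad


def _hybrid_stack(slabs: Sequence[Slab], dz: float, n_sigma: float = 4.5):
    """NC slabs for the buried under-layers, microslices above.

    The stack is sliced from just below the first interface whose roughness
    violates the NC validity rule; everything deeper is kept as discrete
    slabs with NC factors.  Falls back to full microslicing when the seam
    cannot be placed in a quiet region.
    """
    bad = invalid_nc_interfaces(slabs)
    if not bad:
        d, rho, sigma = _stack_arrays(slabs)
        return d, rho, sigma**2
    d, rho, sigma = _stack_arrays(slabs)
    z_if = np.concatenate([[0.0], np.cumsum(d[1:-1])])
    j = bad[0]
    # place the seam n_sigma below the first bad interface, inside slab j;
    # retreat through earlier slabs if the pad does not fit
    while j > 0:
        z_a = z_if[j] - n_sigma * max(sigma[j], 1.0)
        quiet = z_if[j - 1] + 2.0 * sigma[j - 1]
        if z_a > quiet and (j < 2 or z_a > z_if[j - 2]):
            break
        j -= 1
    else:
        return _microsliced_stack(slabs, dz)
    z_b = z_if[-1] + n_sigma * max(sigma[-1], 1.0)
    n = max(int(np.ceil((z_b - z_a) / dz)), 2)
    z = z_a + dz * (np.arange(n) + 0.5)
    prof = np.full(n, rho[0])
    for zi, si, dr in zip(z_if, sigma, np.diff(rho)):
        if si > 0:
            prof += dr * 0.5 * (1.0 + erf((z - zi) / (np.sqrt(2.0) * si)))
        else:
            prof += dr * (z >= zi)
    # under-layer slabs 0..j, slab j truncated at the seam
    trunc = z_a - (z_if[j - 1] if j >= 1 else 0.0)
    d_out = np.concatenate([d[:j], [trunc], np.full(n, dz), [0.0]])
    rho_out = np.concatenate([rho[: j + 1], prof, [rho[-1]]])
    ssq = np.concatenate(
        [sigma[:j] ** 2, np.full(n + 1, -dz * dz / 12.0)]
    )
    return d_out, rho_out, ssq


def abeles_reflectivity(
    slabs: Sequence[Slab],
    q: QGrid | np.ndarray,
    roughness_model: str = "nevot_croce",
    dz: float = 1.0,
) -> np.ndarray:
    """Specular reflectivity |r|² of a slab stack at each Q.

    Parameters
    ----------
    slabs : ordered fronting → backing; at least fronting and backing.
    q : QGrid or array of momentum transfer values [Å⁻¹].
    roughness_model : "nevot_croce", "microslice", "hybrid" or "auto".
        "hybrid" keeps NC slabs for the buried under-layers and microslices
        from the first NC-invalid interface upward; "auto" selects plain NC
        when every interface satisfies the validity rule and "hybrid"
        otherwise.
    dz : sub-slab thickness [Å] used by the microslice treatment.
    """
    if len(slabs) < 2:
        raise ValueError("need at least fronting and backing slabs")
    qv = q.q_values if isinstance(q, QGrid) else np.asarray(q, dtype=float)
    if roughness_model == "nevot_croce":
        d, rho, sigma = _stack_arrays(slabs)
        sigma_sq = sigma**2
    elif roughness_model == "microslice":
        d, rho, sigma_sq = _microsliced_stack(slabs, dz)
    elif roughness_model in ("hybrid", "auto"):
        d, rho, sigma_sq = _hybrid_stack(slabs, dz)
    else:
        raise ValueError(f"unknown roughness_model {roughness_model!r}")
    return _abeles(qv, d, rho, sigma_sq)


def smear_gaussian(
    reflectivity: Callable[[np.ndarray], np.ndarray] | np.ndarray,
    q: QGrid,
    n_points: int = 17,
    n_sigma: float = 3.5,
) -> np.ndarray:
    """Gaussian resolution smearing with FWHM = (dQ/Q)·Q at each point.

    ``reflectivity`` is either a callable ``R(q_array)`` — evaluated on an
    oversampled grid of ``n_points`` quadrature nodes spanning ±``n_sigma``
    standard deviations around each Q — or a precomputed array on ``q``, in
    which case the model between grid points is linearly interpolated in
    log R (adequate only for smooth curves; prefer the callable form).
    """
    qv = q.q_values
    if q.dq_over_q == 0.0:
        return reflectivity(qv) if callable(reflectivity) else np.asarray(reflectivity)
    if callable(reflectivity):
        fn = reflectivity
    else:
        r0 = np.asarray(reflectivity, dtype=float)

        def fn(x, _q=qv, _r=r0):
            return np.interp(x, _q, _r)

    sigma = q.dq_over_q * qv / _FWHM
    u = np.linspace(-n_sigma, n_sigma, n_points)
    w = np.exp(-0.5 * u**2)
    w /= w.sum()
    qs = qv[:, None] + sigma[:, None] * u[None, :]
    qs = np.maximum(qs, 1e-8)
    rs = fn(qs.ravel()).reshape(qs.shape)
    return rs @ w


def smear_fixed_dlogq(
    reflectivity: Callable[[np.ndarray], np.ndarray],
    q: QGrid,
    n_sigma: float = 3.5,
    points_per_sigma: float = 2.5,
) -> np.ndarray:
    """Fast constant-dQ/Q smearing via convolution on a geometric grid.

    A Gaussian whose FWHM is proportional to Q is (to O((dQ/Q)²)) a
    fixed-width Gaussian in ln Q, so the model is evaluated once on a
    log-spaced grid and convolved with a single kernel instead of being
    re-evaluated around every data point.  Agrees with the pointwise
    quadrature of :func:`smear_gaussian` to well below the resolution of
    typical data; preferred inside fitting loops.
    """
    qv = q.q_values
    if q.dq_over_q == 0.0:
        return reflectivity(qv)
    sig_ln = q.dq_over_q / _FWHM
    dln = sig_ln / points_per_sigma
    lo = np.log(qv[0]) - n_sigma * sig_ln
    hi = np.log(qv[-1]) + n_sigma * sig_ln
    n = int(np.ceil((hi - lo) / dln)) + 1
    lnq = np.linspace(lo, hi, n)
    rf = reflectivity(np.exp(lnq))
    m = int(np.ceil(n_sigma * points_per_sigma))
    u = np.arange(-m, m + 1) * dln / sig_ln
    w = np.exp(-0.5 * u**2)
    w /= w.sum()
    rs = np.convolve(rf, w, mode="same")
    return np.interp(np.log(qv), lnq, rs)


def apply_scale_background(
    reflectivity: np.ndarray, scale: float = 1.0, background: float = 0.0
) -> np.ndarray:
    """Map an ideal reflectivity onto the measured scale: scale·R + bkg."""
    if scale <= 0:
        raise ValueError(f"scale must be > 0, got {scale}")
    if background < 0:
        raise ValueError(f"background must be >= 0, got {background}")
    return scale * np.asarray(reflectivity) + background
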
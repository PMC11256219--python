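# Methods

## Interfacial model

The interface is modelled as a stack of laterally-averaged slabs, fronting
to backing: semi-infinite silicon, a mixed SiO₂/permalloy layer, permalloy,
gold, the COOH-OEG-SAM, and — when a membrane is present — a pure-solvent
interlayer, an optional inner protein layer (protein + water only), inner
headgroups, lipid tails, outer headgroups, and a peripheral protein layer,
against semi-infinite solvent.  z = 0 at the silicon surface, increasing
toward solution; the beam enters through the silicon (inverted solid–liquid
geometry).

Each layer carries a thickness, component volume fractions and the Gaussian
roughness σ of its top (solution-side) interface.  Within every layer
lipid + protein (+ SAM, etc.) ≤ 1 and solvent fills the remainder, enforced
at render time.  Inner and outer headgroups are symmetric (same thickness
and composition) by default, matching the resolved structure; asymmetry is
available by constructing the model with `symmetric_heads=False`.  One
`bilayer_roughness` applies to all membrane-internal interfaces (including
the interlayer top); the peripheral layer's outer interface has its own
roughness.  The optional inner protein layer defaults to zero thickness —
in the resolved structures the protein asymmetry is carried by the
peripheral layer — and zero-thickness layers are skipped when rendering
slabs (they are exactly invisible to the reflectivity).

### Component SLDs and contrasts

SLDs are in 1e-6 Å⁻² throughout.  Defaults (all overridable): Si 2.07,
SiO₂ 3.47, permalloy 8.5, Au 4.5, SAM 0.3/0.6 (H₂O/D₂O, partial carboxyl
exchange), lipid tails −0.4, PC/PS headgroups 1.85/1.92, hydrogenous
protein 1.9/3.2.  Water endpoints are −0.56 (H₂O, Σb/V with V = 30.0 Å³)
and 6.36 (D₂O, the standard tabulated value).  Labile-hydrogen exchange is
modelled as complete and linear in the solvent D₂O fraction.  Named
contrasts: D2O (1.0), AuMW (0.75, gold-matched), PrMW (0.42,
protein-matched), H2O (0.0).  Absorption (imaginary SLD) is neglected —
negligible for these isotopes at cold-neutron wavelengths.

## Reflectivity kernel

The Abelès 2×2 characteristic-matrix recursion gives |r|² per Q for the
slab stack (numba-accelerated with an identical pure-numpy fallback).
Roughness treatments:

- **Névot–Croce**: each interfacial Fresnel coefficient is damped by
  exp(−2 k_a k_b σ²).  Fast and accurate while σ is small relative to the
  adjacent thicknesses; it degrades to ~2–3×10⁻³ relative error by
  σ ≈ 5 Å at Q = 0.3 Å⁻¹.
- **Microslice**: the erf-broadened SLD profile is discretized into 1 Å
  sub-slabs.  Midpoint discretization of a smooth profile is equivalent to
  convolving it with a 1 Å box, which systematically damps the computed
  reflectivity by ≈ (Q·dz)²/12; each sub-slab interface therefore carries
  an effective σ² = −dz²/12 that deconvolves the box exactly.  With this
  correction the dz = 1 Å staircase matches a dz = 1/32 Å reference to
  ~5×10⁻⁶ relative on smooth profiles.  (For profiles with genuinely hard
  steps the correction slightly over-sharpens; such stacks are handled by
  Névot–Croce, for which hard steps are exact.)
- **Hybrid/auto** (default in the pipeline): plain Névot–Croce when every
  interface satisfies σ < ⅓ × adjacent thickness, otherwise discrete NC
  slabs for the buried under-layers and microslices from just below the
  first NC-invalid interface upward (the seam is placed 4.5σ inside the
  layer below, in a quiet region).  The membrane region — where σ can reach
  68 Å against 8 Å headgroup layers in the EDTA state — is therefore always
  sliced, while the thick metal under-layers stay cheap.

### Resolution smearing

Instrument resolution is Gaussian with FWHM = (dQ/Q)·Q, default
dQ/Q = 3.5% (FWHM convention, matching time-of-flight reporting).  Two
implementations: `smear_gaussian`, pointwise 17-node quadrature over
±3.5σ around every data point (the reference, validated against brute-force
fine-grid convolution), and `smear_fixed_dlogq`, which exploits that a
constant-dQ/Q Gaussian is a fixed-width kernel in ln Q, evaluating the model
once on a geometric grid (≈2.5 points per σ) and convolving.  Both agree
with brute force to ~1% (the difference is concentrated at the
critical-edge kink); the fast path is used inside fitting loops, and because
simulation and fitting share it, round-trip studies are exactly
self-consistent.

## Profiles

Component volume-fraction profiles are sums of erf-edged boxcars on a 1 Å
grid; water is the unoccupied volume, so fractions sum to one at every
point.  When a very rough edge's erf tail reaches back into an
already-full region (possible when σ ≫ the interlayer thickness), occupancy
is saturated at 100% by proportional rescaling.  The grid extends 4σ past
the outermost interface.  SLD profiles are Σ fraction × component SLD plus
solvent; microslicing this profile and running the kernel reproduces the
slab+NC calculation in the small-roughness regime (tested).

## Co-refinement

All datasets of an experiment share one `Underlayers` object (sharing is by
Python object identity), each salt condition has its own membrane model,
and every dataset carries scale (bounds 0.8–1.2) and background (0–1e-4)
nuisance parameters, fixed by default and fittable on request.  The
objective is χ² with the model evaluated on each dataset's own Q grid
(datasets are never interpolated onto each other).  Optimization:
differential evolution (rand-to-best/1/bin as implemented by scipy,
`updating="immediate"`, population 12–15 × n_params, tol 0.005, bounds
required on every free parameter, seeded) followed by a bounded trust-region
least-squares polish.  χ² is non-increasing through the polish by
construction.

## DRAM uncertainty quantification

The posterior is exp(−χ²/2) with uniform priors on the bounds.  The sampler
is Delayed-Rejection Adaptive Metropolis: a Gaussian random-walk first
stage; on rejection, a second proposal with covariance scaled by 1/5²; and
adaptation of the proposal covariance every 100 steps (from step 200) to
2.38²/d × the chain covariance plus a small diagonal jitter.  The initial
proposal covariance is the Gaussian approximation (JᵀJ)⁻¹ from the weighted
residual Jacobian at the start point (typically the polished fit), capped at
a quarter of each bound width.  The first 25% of steps are discarded as
burn-in (configurable).  Total acceptance rates around 0.6–0.9 are normal
for DRAM — the narrow second stage accepts most delayed tries — and the
sampler is validated against analytic Gaussian posteriors and an emcee
cross-check rather than by acceptance rate.  Zero accepted proposals raises
a diagnostic error.

Parameter uncertainties are shortest 65% percentile intervals: the
narrowest contiguous window of sorted samples containing ⌈0.65 n⌉ draws
(leftmost on ties; at least 50 samples required).  Curve uncertainties come
from recomputing reflectivities and profiles for draws resampled from the
chain (1000 by default) and taking pointwise means ("best fit" lines) and
shortest-65% envelopes; profile envelopes are evaluated on a fixed z grid
wide enough for every draw.

## Synthetic data generator

Emulates SURF-style (0.5–7 Å band; 0.35°/0.65°/1.5°) and INTER-style
(1–16 Å; 0.7°/2.3°) time-of-flight measurements: 150 log-spaced Q bins over
the accessible range clipped to 0.009–0.3 Å⁻¹, dQ/Q = 3.5%, and
counting-statistics noise via an effective-count model
N_eff(Q) = counting_time × A (Q/Q₀)⁻ᵖ with A = 10⁶, p = 2, Q₀ = 0.003 Å⁻¹,
giving dR = R/√N_eff ≈ 0.3% relative on the total-reflection plateau and
≈10% at Q = 0.3 Å⁻¹ — figure-quality data.  R is drawn from N(R_model, dR);
χ² at the generating truth therefore averages one per point (tested over
100 seeds).  Infinite counting time returns the exact model curve with a
nominal 10⁻⁸ relative uncertainty so the likelihood stays defined.

The bundled ground truth is the resolved membrane structure (25 Å SAM at
92% coverage with 9 Å roughness; 11 Å interlayer; 8 Å heads at 42% lipid /
24% protein; 30 Å tails at 61% lipid / 24% protein; 50.5 Å peripheral
protein at 13%; bilayer roughness 7 Å) plus the two salt-shifted states
(interlayer 26 Å / roughness 16 Å with added NaCl; 132 Å / 68 Å in EDTA).
Under-layer values not reported experimentally (oxide/metal thicknesses)
are conventional magnetron-sputtered-film values: 10 Å mixed oxide layer,
150 Å permalloy, 100 Å gold, 3–5 Å roughnesses.
`make_condition_series` produces the full 14-dataset sequence (2 bare + 3
conditions × 4 contrasts).

What the generator does **not** emulate: real count-rate spectra and
angle-stitching artifacts, detector efficiency and gravity corrections,
off-specular scattering, sample-to-sample coverage variation, incoherent
background structure (the background is a flat 10⁻⁶), or magnetic contrast
from the permalloy.  Passing round-trip tests therefore demonstrates the
correctness and calibration of the analysis machinery under the stated
noise model, not the information content of any particular real
measurement.

## Problem sizes and settings used in the test suite

Round-trip acceptance fits use the full 150-bin INTER grid with six (or
four) datasets and five (or two) free parameters — the headline structural
parameters, with remaining parameters held at their generating values, a
deliberate demonstration scale that keeps the fits well identified.
Calibration studies use a reduced 60-bin grid, single-contrast replicates,
and 1200-step chains; 20 replicates give 40 binomial coverage trials for
the 65% intervals.  The pipeline demo runs a 2-dataset bare-surface fit
with a 400-step chain.

## Degenerate inputs and edge cases

Zero-thickness layers are dropped from slab rendering (provably no effect
on R).  Zero roughness uses hard steps.  Constant (zero-variance) posterior
columns yield zero-width intervals.  Datasets must have strictly positive
dR and ascending Q (descending input is sorted with a warning).  A fit
problem without bare-surface datasets warns that under-layers may be
unidentifiable.  `run_dram` on a problem with no varying parameters raises.

## Known limitations

Single-model slab description (no lateral inhomogeneity beyond in-plane
averaging, no multimodal model selection); no absorption or magnetic
reflectivity; Névot–Croce validity is enforced only through the ⅓-rule
heuristic; the QCM module deliberately stops at penetration depths and
Sauerbrey conversion (no Voigt viscoelastic modelling).
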
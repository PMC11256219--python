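# floatnr

Neutron reflectometry (NR) analysis of *floating* protein–lipid membranes:
self-assembled bilayers containing an integral membrane-protein complex
(BamABCDE in POPC:POPS) that hover above a carboxyl-OEG self-assembled
monolayer (SAM) on a gold/permalloy-coated silicon substrate, separated from
it by a tunable water interlayer.

The package is for reflectometrists and membrane biophysicists who want a
scriptable, testable version of this analysis: a constrained volume-fraction
slab model of the Si / SiO₂–permalloy / permalloy / Au / SAM / water /
membrane interface, co-refined simultaneously against several solvent
isotopic contrasts (100% D₂O, gold-matched water, protein-matched water,
100% H₂O), with Bayesian uncertainty quantification and an
instrument-realistic synthetic-data generator for end-to-end validation.

## The model

Specular reflectivity is computed from the scattering-length-density (SLD)
depth profile ρ(z) with the Abelès optical-matrix recursion over slabs, as a
function of momentum transfer

    Q_z = 4π sin(θ) / λ,

with Gaussian interfacial roughness handled either by Névot–Croce damping
factors or by microslicing the erf-broadened profile into 1 Å sub-slabs
(required when roughness becomes comparable to layer thickness, as in the
EDTA-driven large-distance state).  Each layer is described by volume
fractions of chemical components (SAM, lipid heads/tails, protein) with
solvent filling the remainder, so that Σ fractions = 1 everywhere; layer
SLDs follow from the component SLDs at each solvent contrast.  All datasets
— two bare-surface contrasts measured before membrane deposition and four
contrasts per membrane condition — share one set of under-layer parameters.

Fitting minimizes χ² = Σ_i ((R_model,i − R_i)/dR_i)² with a
differential-evolution global stage plus bounded least-squares polish;
uncertainties come from Delayed-Rejection Adaptive Metropolis (DRAM) MCMC
sampling of exp(−χ²/2), summarized as shortest 65% percentile intervals and
resampled reflectivity/SLD/volume-fraction envelopes.  A small QCM-D module
provides the shear-wave penetration depth δ = √(η/(πρf₀n)) and Sauerbrey
mass–frequency conversions used in the depth-sensitivity argument.

## Worked example

Simulate the four-contrast calcium-state experiment from the published
structure, co-refine it with shared under-layers, and look at the recovered
membrane:

```python
import numpy as np
import floatnr as F

truth = F.default_ground_truth()            # resolved structures as truth
seeds = np.random.SeedSequence(1).generate_state(6)
data = [F.simulate_dataset(truth.underlayers, None, F.INTER, c, int(s))
        for c, s in zip(("D2O", "H2O"), seeds)]          # bare surface
data += [F.simulate_dataset(truth.underlayers, truth.membranes["Ca"],
                            F.INTER, c, int(s), condition="Ca")
         for c, s in zip(("D2O", "AuMW", "PrMW", "H2O"), seeds[2:])]

fit = F.default_ground_truth()
problem = F.FitProblem(fit.underlayers, data,
                       membranes={"Ca": fit.membranes["Ca"]})
for name in ("sam_coverage", "interlayer_thickness", "tails_thickness",
             "tails_lipid_fraction", "bilayer_roughness"):
    problem.find_parameter(name).vary = True
F.fit_global(problem, seed=7)
F.fit_local(problem)
for p in problem.varying_parameters():
    print(f"{p.name}: {p.value:.3f}")
```

prints (seed 7, ≈2–3 min on one CPU):

```
sam_coverage: 0.919
interlayer_thickness: 10.980
tails_thickness: 30.004
tails_lipid_fraction: 0.612
bilayer_roughness: 7.034
```

i.e. the fit recovers the generating structure — a 92%-coverage SAM, an
11 Å water interlayer, and a 30 Å lipid-tails region containing 61% lipid —
to well within the experimental 65% confidence widths.  χ²/N ≈ 1.05 over
the 900 points, consistent with the counting-statistics noise model.
`F.run_dram(problem, n_steps=5000, seed=8)` then yields the posterior with
shortest-65% intervals, and `F.posterior_bands` the uncertainty envelopes.

The QCM-D depth-sensitivity table:

```sh
$ floatnr qcm --overtones 3,5,7
overtone	frequency_MHz	penetration_depth_nm
3	15.0	121
5	25.0	93
7	35.0	79
```

A YAML-driven pipeline (`floatnr simulate | fit | profile`) wraps the same
functionality; see `examples/demo.yml`.

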
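# Demo pipeline: simulate a small bare-surface + membrane experiment from
# the bundled ground truth, co-refine it, and quantify uncertainty.
# Run:  floatnr fit --config examples/demo.yml --out results/demo
# Units: lengths in Angstrom, Q in 1/Angstrom, SLD in 1e-6/Angstrom^2.
seed: 1
output_dir: results/demo
instrument: INTER
roughness_model: auto

underlayers:
  sam_thickness: {value: 25.0, bounds: [18, 32], vary: true}
  sam_coverage: {value: 0.92, bounds: [0.7, 1.0], vary: true}

membranes:
  Ca:
    interlayer_thickness: {value: 11.0, bounds: [3, 25], vary: true}
    tails_thickness: {value: 30.0, bounds: [20, 40], vary: true}

simulate:
  counting_time: 1.0
  datasets:
    - {contrast: D2O, phase: bare}
    - {contrast: H2O, phase: bare}
    - {contrast: D2O, phase: membrane, condition: Ca}
    - {contrast: H2O, phase: membrane, condition: Ca}

fit:
  fit_scale: false
  fit_background: false
  optimizer: {popsize: 10, maxiter: 25, tol: 0.005}
  mcmc: {steps: 1500, burn_fraction: 0.25}
  bands: {draws: 200}
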
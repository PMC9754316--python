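# Trihydrogen cation in DMSO: the package's canonical benchmark run.
geometry: h3+
optimize_geometry: true      # equilateral side minimized at FCI/STO-3G
solvent:
  epsilon: 46.7              # DMSO
  tess_level: 3
ansatz:
  threshold: 1.0e-5          # Ha/rad gradient screen
optimizer:
  name: adaptive_gd
  tol: 1.0e-8
seed: 0
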
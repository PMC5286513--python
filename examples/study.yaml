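# Full study recipe for `shapeatlas run`: simulate (or load a manifest),
# build one atlas per subpopulation in the plan, run every comparison.
out: study_out
seed: 7

simulation:                 # alternatively: `manifest: path/to/manifest.csv`
  groups:
    - {n: 10, label: PCaPos, institution: 1}
    - {n: 10, label: BxNeg, institution: 2, bump_amplitude: 5.0}
  two_raters: true
  rater_jitter_mm: 0.6

atlas:
  spacing_mm: 2.0           # atlas grid (isotropic, mm)
  margin_mm: 12.0
  weights: {w_intensity: 1.0, w_prostate: 1.0, w_cg: 1.0}
  registration:
    band_mm: 10.0
    elastic_ctrl_spacing_mm: 15.0
    elastic_cap_mm: 10.0

comparison:
  alpha: 0.05
  band_mm: 3.0

plan:
  - a: {group: PCaPos, rater: 1}
    b: {group: BxNeg, rater: 1}
  - a: {group: PCaPos, rater: 1}
    b: {group: PCaPos, rater: 2}
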
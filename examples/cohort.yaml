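# Cohort recipe for `shapeatlas simulate`.
# Every GroupSpec field is shown with its default; `base:` overrides
# PhantomParams (semiaxes in mm, angles in degrees).
groups:
  - n: 10
    label: PCaPos            # group tag: PCaPos, BxNeg or ClNeg
    institution: 1           # ClNeg only at 1, BxNeg only at 2 or 3
    scale_sd: 0.15           # fractional sd of the volume scale factor
    shape_sd: 0.04           # fractional per-axis semiaxis spread
    surface_noise_mm: 0.8    # RMS of the smooth per-subject surface irregularity
    rotation_sd_deg: 5.0
    translation_sd_mm: 3.0
    bump_amplitude: 0.0      # focal posterior CG bump, mm
    hypertrophy_factor: 1.0  # multiplies CG volume
  - n: 10
    label: BxNeg
    institution: 2
    bump_amplitude: 5.0
    hypertrophy_factor: 2.0
    base:
      prostate_semiaxes: [22.0, 18.0, 20.0]
      cg_semiaxes: [14.0, 10.0, 12.0]
      cg_offset: [0.0, -2.0, 2.0]
      bump_center: [0.0, 1.0, 0.5]   # posterior-superior direction
      bump_width_deg: 35.0
      noise_sd: 8.0
      bias_field: none               # or: endorectal

two_raters: true
rater_jitter_mm: 0.6
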
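name: framingham_offspring
family: weighted_logistic
provenance: >
  Framingham Offspring simple clinical model for incident type 2 diabetes
  (Wilson et al., Arch Intern Med 2007), logistic form. The male-sex
  coefficient -0.01 is the value quoted in the cohort analysis this package
  reimplements; the remaining coefficients are an approximate transcription
  reconstructed in proportion to the published points system and MUST be
  verified against the source publication before any substantive use. This
  file is editable config data; the engine, not these numbers, is the
  package contract. Variant: simple clinical model (no 2-h glucose, no
  insulin/CRP terms).
intercept: -5.517
terms:
  - field: sex
    type: categorical
    mapping:
      male: -0.01
      female: 0.0
  - field: family_history_diabetes
    type: flag
    value_true: 0.573
  - field: bmi
    type: cut
    bins:
      - [-.inf, 25.0, 0.0]
      - [25.0, 30.0, 0.25]
      - [30.0, .inf, 0.81]
  - field: elevated_bp
    type: flag
    value_true: 0.423
  - field: hdl_low
    type: flag
    value_true: 0.495
  - field: tg_high_150
    type: flag
    value_true: 0.348
  - field: ifg
    type: flag
    value_true: 1.942
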
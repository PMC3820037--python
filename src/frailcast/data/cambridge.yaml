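name: cambridge
family: weighted_logistic
provenance: >
  Cambridge diabetes risk score, logistic-model form (Griffin et al.,
  Diabetes Metab Res Rev 2000). Coefficients transcribed from the published
  model as commonly reproduced; this file is editable config data and should
  be checked against the source publication before clinical use. The female
  coefficient -0.879 (prints as -0.88) is the value quoted in the cohort
  analysis this package reimplements.
intercept: -6.322
terms:
  - field: sex
    type: categorical
    mapping:
      male: 0.0
      female: -0.879
  - field: age
    type: linear
    coefficient: 0.063
  - field: bmi
    type: cut
    bins:
      - [-.inf, 25.0, 0.0]
      - [25.0, 27.5, 0.699]
      - [27.5, 30.0, 1.97]
      - [30.0, .inf, 2.518]
  - field: family_history_diabetes
    type: flag
    value_true: 0.728
  - field: smoking
    type: categorical
    mapping:
      non: 0.0
      former: -0.218
      current: 0.855
  - field: antihypertensive_rx
    type: flag
    value_true: 1.222
  - field: corticosteroid_rx
    type: flag
    value_true: 2.191
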
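name: findrisc
family: categorical_points
provenance: >
  Finnish diabetes risk score, full 8-item version (Lindstrom & Tuomilehto,
  Diabetes Care 2003). Points transcribed from the published score; the
  physical-activity item is mapped to the cohort's >=4 h/wk indicator and
  the family-history item to the parent/sibling flag (first-degree history,
  5 points). Editable config data.
terms:
  - field: age
    type: cut
    bins:
      - [-.inf, 45.0, 0]
      - [45.0, 55.0, 2]
      - [55.0, 65.0, 3]
      - [65.0, .inf, 4]
  - field: bmi
    type: cut
    bins:
      - [-.inf, 25.0, 0]
      - [25.0, 30.0, 1]
      - [30.0, .inf, 3]
  - field: waist
    type: cut_by_sex
    bins_by_sex:
      male:
        - [-.inf, 94.0, 0]
        - [94.0, 102.0, 3]
        - [102.0, .inf, 4]
      female:
        - [-.inf, 80.0, 0]
        - [80.0, 88.0, 3]
        - [88.0, .inf, 4]
  - field: physical_activity_4h
    type: flag
    value_true: 0
    value_false: 2
  - field: daily_fruit_veg
    type: flag
    value_true: 0
    value_false: 1
  - field: antihypertensive_rx
    type: flag
    value_true: 2
    value_false: 0
  - field: history_high_glucose
    type: flag
    value_true: 5
    value_false: 0
  - field: family_history_diabetes
    type: flag
    value_true: 5
    value_false: 0
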
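# Methods

This note documents the models implemented in `frailcast`, the parameter
choices that matter, what the synthetic cohort does and does not emulate,
and the numerical conventions. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Study design being modelled

A prospective occupational cohort: diabetes risk factors measured at a
baseline clinical examination, three published diabetes risk algorithms
computed from them, and the Fried frailty phenotype assessed roughly ten
years later. Prevalent diabetes at baseline is excluded from the main
analytic sample. Frailty is dichotomized (prefrail/frail vs nonfrail)
because frank frailty is rare (~3%). The scientific questions are (a)
which individual risk factors predict frailty, and (b) whether the risk
algorithms — built to predict diabetes — also discriminate future frailty,
and how strongly relative to one another.

## Fried phenotype operationalisation

Five binary components; score = number positive; 0 → nonfrail,
1–2 → prefrail, ≥ 3 → frail.

| component | rule |
|---|---|
| exhaustion | either CES-D item ("everything was an effort", "could not get going") endorsed at 3–4 or 5–7 days/week |
| low activity | energy expenditure < 383 kcal/wk (men), < 270 (women); expenditure = Σ MET × hours × body mass, 1 MET = 1 kcal·kg⁻¹·h⁻¹ |
| slow walking | 8-ft time ≥ 3.73 s if height ≤ 173 cm (men) / ≤ 159 cm (women), else ≥ 3.20 s |
| weak grip | max grip ≤ sex/BMI-stratified cut-off (men: 29/30/32 kg over BMI ≤24 / (24,28] / >28; women: 17/17.3/18/21 kg over ≤23 / (23,26] / (26,29] / >29) |
| weight loss | > 10% decrease between the two weighings ~5 y apart (strict inequality) |

Conventions the published wording leaves open, fixed here:

- The energy formula itself (MET × hours × mass) is fixed explicitly; a
  `reference_mass_kg` switch (e.g. 60 kg) supports weight-free
  questionnaire pipelines.
- BMI strata for grip are half-open on the right, (24, 28] etc., so every
  BMI value falls in exactly one stratum despite the "≤24 / 24.1–28.0"
  printed banding.
- Grip is the maximum over available dynamometer trials.
- The exhaustion response taxonomy is fixed to the four CES-D frequency
  categories; unlisted strings are rejected, never coerced.
- With partially missing components the status is reported only when
  already forced: ≥ 3 observed positives → frail; ≥ 1 positive with no
  path to 3 → prefrail; all five observed negative → nonfrail; otherwise
  missing. The pipeline's default behaviour, like the source analysis, is
  to exclude participants with undetermined frailty.
- An abstract-style reading ("prefrail = 2 or fewer") would fold nonfrail
  into prefrail; the three-level 0 / 1–2 / ≥3 mapping is implemented.
- Whether weight loss must be unintentional is unknowable from the data;
  no intent filter is applied.
- A sensitivity mode drops the physical-activity component and scores out
  of 4 with the same 0 / 1–2 / ≥ 3 mapping, removing the overlap between
  the frailty scale and activity-containing risk scores.

## Risk-score engines

Score definitions are data, not code: YAML files with typed additive terms
(linear, flag, categorical mapping, half-open numeric cuts, sex-stratified
cuts), validated against the cohort column dictionary (existence,
non-overlap, exhaustiveness, integer points for the points family). The
engine evaluates terms deterministically, converts units per the
definition's declarations (glucose mg/dL ↔ mmol/L at exactly 18.0),
propagates missing inputs to a missing score with a per-field missingness
report, and never refits or recalibrates anything.

For the weighted-logistic family the score is the linear predictor, not
the predicted probability: per-SD odds ratios are invariant to monotone
rescaling and the linear predictor avoids compression near probability 0/1.

The three shipped definitions are editable transcriptions of the published
algorithms. The FINDRISC points and Cambridge coefficients follow the
published models; the Framingham Offspring file is an approximate
reconstruction (coefficients proportional to the published points system,
with the quoted male-sex coefficient −0.01) and its provenance note says
so — the engine, not the shipped numbers, is the package contract. The
Framingham variant recorded is the simple clinical model. Config tests pin
the two externally quoted values: female − male = −0.88 (Cambridge) and
male − female = −0.01 (Framingham) at printed precision.

## Cohort conventions

- Canonical units: glucose mmol/L, lipids mg/dL; the conversion factor is
  exactly 18.0 so the 7.0 mmol/L diabetes threshold coincides with
  126 mg/dL and the impaired-fasting-glucose band 100–<126 mg/dL is
  half-open against it. Band membership is evaluated at integer mg/dL
  precision, so a value recorded as 5.55 mmol/L counts as 100 mg/dL.
- Diabetes: fasting ≥ 7.0 mmol/L, 2-h post-load ≥ 11.1 mmol/L, physician
  diagnosis, or diabetes medication *in the presence of* a diagnosis;
  medication alone does not classify. Classification is monotone in both
  glucose values.
- BMI categories are half-open: [25, 30) is the middle band.
- Missing values propagate as missing everywhere; imputation is an explicit
  pipeline stage, never a silent default.

## Association statistics

- Logistic fits use IRLS with a score-norm tolerance of 1e-8 and at most
  100 iterations. Rank deficiency is detected by pivoted QR and reported
  with column names; diverging coefficients (|β| > 30, the signature of
  complete separation) raise a flagged error rather than returning
  meaningless estimates. Wald CIs are exp(β ± z₀.₉₇₅·SE). The solver is
  cross-checked in the tests against closed-form 2×2 fits and an
  independent reference implementation at 1e-6.
- BCa bootstrap: bias constant z₀ = Φ⁻¹((#{θ* < θ̂} + ½#{θ* = θ̂})/B) with
  the half-tie rule, acceleration from the leave-one-out jackknife
  third-moment formula, adjusted percentile levels mapped through Φ.
  Degenerate bootstrap distributions collapse to a point with a warning;
  one-sided θ* configurations clamp the counting proportion to
  (1/(2B), 1 − 1/(2B)) to keep z₀ finite. B defaults to 2000 per the
  source procedure; tests and example pipelines use B = 200–500 as this
  package's own desk-scale default run sizes.
- OR differences are taken on the OR scale (Δ = OR_b − OR_a), matching how
  such comparisons are printed, not on the log-OR scale — the two differ.
  Whole records are resampled jointly and scores are re-standardized
  within each resample so the interval carries the sampling variability of
  the standardisation.
- AUC is the Mann–Whitney estimator with ties counted ½ (equal to the
  trapezoidal ROC area). The AUC-difference CI defaults to the paired BCa
  bootstrap for consistency with the OR-difference procedure; the source
  analysis does not state its method, and a DeLong correlated-curves
  variance is provided as the alternative (the pipeline's Table-3 report
  uses DeLong for speed).
- Sex interaction: Wald test on the z×sex product term in a model with
  both main effects; invariant to which sex is coded 1.
- The "fully adjusted" model enters age, BMI, waist, SBP, DBP, fasting
  glucose, HDL and triglycerides linearly, sex and the treatment/lifestyle
  indicators as 0/1 flags, and smoking as two indicators against
  never-smoking. The source does not state the coding for every factor;
  this choice is recorded here and in `pipeline.ADJUSTMENT_*`.
- Table-1 heterogeneity uses the chi-square test without continuity
  correction for categorical factors. For age the source names the
  signed-rank test, which is a paired test; the two frailty groups are
  independent samples, so the rank-sum (Mann–Whitney) test is used
  instead. No multiple-testing correction is applied.

## Multiple imputation

Chained equations sweep variables in declared order (default 10 sweeps,
m = 20 completed datasets; the source analysis used 200 — m is
configurable and 20 is this package's desk-scale default with the same
estimator structure). Conditionals: Bayesian linear regression (σ² from
its scaled inverse-χ² posterior, β from its normal posterior) with
predictive mean matching over k = 5 donors for continuous variables;
logistic with an asymptotic-normal parameter draw for binaries;
multinomial at the MLE for categoricals (no parameter draw — a documented
approximation that slightly understates uncertainty for categorical
conditionals). All draws come from a single seeded generator, so identical
spec + seed reproduces imputations bitwise. Pooling follows Rubin's rules
with Barnard–Rubin degrees of freedom when the complete-data df is
supplied. The analysis frame for imputation (who enters the imputation
model) is the caller's choice — the pipeline imputes the score-input
columns of the filtered analytic table.

## Synthetic cohort: what it emulates, and what it does not

The generator's defaults are the study conditions:

- n = 2707; age ~ Normal(55.0, 5.9) truncated to [45, 69] (truncation
  lifts the realised mean by ≈ 0.5 y — the printed 55.0 describes the
  already-truncated sample); 27.9% women; every categorical risk-factor
  marginal taken from the printed baseline table's counts (the smoking
  row's printed percentages are internally inconsistent, so the counts
  1514/967/226 are used). History of high blood glucose is not printed;
  0.15 is assumed, near the impaired-fasting-glucose rate.
- Categoricals are drawn by thresholding an exchangeable Gaussian copula
  (default latent ρ = 0.15 — a modest, arbitrary default standing in for
  unreported risk-factor correlations), then a continuous value is drawn
  uniformly within the category's numeric band, so derived categories
  reproduce the marginals exactly while score engines get continuous
  inputs. The uniform-within-band shapes are not realistic marginal
  densities; only the category structure is calibrated.
- Fried components are five exchangeable binaries from one latent factor:
  component_j = 1{√ρ·G + √(1−ρ)·ε_j < Φ⁻¹(p)}. The two moments
  P(score = 0) = 0.597 and P(score ≥ 3) = 0.028 identify (p, ρ); the
  solver nests a monotone root-find for p inside a root-find for ρ with
  residuals < 1e-3 (Gauss–Hermite quadrature over the shared factor,
  80 nodes). Independence (ρ = 0) provably cannot satisfy both moments:
  with P(score=0) = 0.597, P(score ≥ 3) stays below 1%. The exchangeable
  one-factor structure is the simplest model matching the two printed
  prevalence moments; real component correlations are unreported and
  surely not exchangeable.
- In end-to-end cohorts the shared factor loads (λ = 0.3) on a composite
  of the three standardized scores with weights solved from the scores'
  correlation matrix so each score's marginal loading is proportional to
  its printed frailty log-OR (1.05 : 1.18 : 1.27) — the small negative
  Framingham weight is what that ordering requires given the weak
  inter-score correlations. This preserves the printed effect ordering as
  a property of the data-generating process; the absolute pipeline ORs on
  synthetic data are qualitative, not calibrated equalities.
- Outcome flags are Bernoulli(logit⁻¹(α + β·z)) with β = log(per-SD OR)
  and α solved so the mean simulated risk hits the target prevalence
  (frailty/prefrailty 40.3%, incident diabetes 8.9%). These layers drive
  the parameter-recovery tests against the printed per-SD ORs.
- Raw follow-up measures (walk time, grip, CES-D responses, energy,
  follow-up weight) are back-filled uniformly on the correct side of each
  published threshold, so re-classifying the raw measures recovers the
  component indicators exactly and end-to-end runs exercise the real
  classification rules. The raw-measure distributions are not realistic;
  they exist to test the classifiers, not to emulate physiology.
- Missingness injection: MCAR (iid) or MAR (deletion probability logistic
  in standardized fully observed covariates with unit slopes and a
  rate-calibrated intercept).

Because of these simplifications, passing tests demonstrate that the
pipeline recovers known data-generating parameters and preserves the
configured structure — not that the original cohort's adjusted estimates
would be reproduced. The real-data adjusted ORs, AUC levels, OR
differences and the sex-interaction p-value depend on the original data,
which are not redistributable; the pipeline reproduces their report
structure and the recovery tests target their printed values.

## Numerical conventions and degenerate inputs

- All randomness flows through `numpy.random.Generator` objects; every
  public stochastic function takes a seed or generator, and fixed seeds
  reproduce outputs bitwise.
- Standardisation uses the sample SD (n − 1); constant scores are an
  error, and the SD and mean are logged for audit.
- Verification problem sizes (chosen as this package's standard run
  sizes): status-prevalence calibration is checked at n = 10⁶; per-SD OR
  recovery at n = 10⁵ with 50 replicates; BCa coverage at 1000 datasets
  with B = 500; imputation coverage at 500 replicates with m = 10.
- Empty Table-1 strata report missing percentages and are flagged rather
  than raising.
- Presentation rounding (ORs 2 dp, percentages 1 dp) happens only in the
  human-readable report; CSVs keep full precision.

## Known limitations

- The Framingham Offspring coefficients are an approximate transcription;
  replace `src/frailcast/data/framingham_offspring.yaml` with verified
  values before any substantive use.
- The multinomial imputation conditional omits the parameter draw.
- The copula's exchangeable correlation is a single knob; it cannot
  express realistic factor-specific dependence (e.g. BMI–waist ≫
  BMI–smoking).
- No MNAR missingness, no survival modelling, no score recalibration, and
  no alternative frailty instruments.
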
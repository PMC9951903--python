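name: model_05_mattioli_2016
n_compartments: 1
theta:
  cl: 2.18
  vc: 8.3
relations:
- target: cl
  covariate: sepsis_level
  form: categorical_factor
  reference_value: 1.0
  coefficient: 0.75
  category: severe sepsis/septic shock
- target: vc
  covariate: albumin
  form: power
  reference_value: 25.0
  coefficient: -0.5
- target: vc
  covariate: age
  form: power
  reference_value: 68.0
  coefficient: 0.5
eta_names:
- cl
- vc
omega:
- - 0.09
  - 0.0
- - 0.0
  - 0.0625
residual:
  kind: combined
  sigma_add: 0.5
  sigma_prop: 0.2
source_note: 'Approximate encoding of Mattioli et al. 2016 (ICU nosocomial infection;
  no renal covariate): typical values from the published summary table; covariate
  relation forms/coefficients and variance components are placeholders (exact equations
  live in the source publication).'
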
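name: model_09_lonsdale_2020
n_compartments: 2
theta:
  cl: 8.7
  vc: 8.8
  q2: 13.8
  vp2: 10.6
relations:
- target: cl
  covariate: age
  form: power
  reference_value: 55.0
  coefficient: -0.25
- target: cl
  covariate: weight_total
  form: power
  reference_value: 70.0
  coefficient: 0.75
- target: vc
  covariate: weight_total
  form: linear_proportional
  reference_value: 70.0
  coefficient: 1.0
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
source_note: 'Approximate encoding of Lonsdale et al. 2020 (neonatal-to-elderly critical
  illness; no renal covariate): typical values from the published summary table; covariate
  relation forms/coefficients and variance components are placeholders (exact equations
  live in the source publication).'
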